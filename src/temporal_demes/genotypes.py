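"""Grouped co-dominant genotype container.

The central in-memory object shared by the statistics, DAPC and IO modules:
diploid multi-allelic calls (microsatellite sizes or diallelic {1, 2} codes)
for a set of individuals carrying arbitrary group labels (site, year,
developmental stage, deme ...).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing call (both copies of the pair are set to it)
MISSING = -1


class GroupedGenotypes:
    """Diploid genotypes with group labels.

    Parameters
    ----------
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele codes
        are arbitrary non-negative integers, a missing call is ``(-1, -1)``.
        Pairs are unordered and stored sorted.
    loci
        Locus names, length ``n_loci``.
    labels
        One row per individual; every column is a grouping variable
        (e.g. ``site``, ``year``, ``stage`` or ``deme``). The index holds
        individual identifiers.
    """

    def __init__(self, calls: np.ndarray, loci: Sequence[str], labels: pd.DataFrame):
        calls = np.asarray(calls)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        if calls.shape[1] != len(loci):
            raise ValueError("loci length does not match calls")
        if len(labels) != calls.shape[0]:
            raise ValueError("labels length does not match calls")
        calls = calls.astype(np.int64, copy=True)
        # a call with either copy missing is treated as wholly missing
        half_missing = (calls < 0).any(axis=2)
        calls[half_missing] = MISSING
        calls.sort(axis=2)  # canonical unordered pair
        self.calls = calls
        self.loci = list(loci)
        self.labels = labels.copy()

    # ------------------------------------------------------------------ basics
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_individuals

    def scored_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is present."""
        return self.calls[:, :, 0] >= 0

    def alleles(self, locus: int) -> np.ndarray:
        """Sorted distinct allele codes observed at ``locus``."""
        col = self.calls[:, locus, :]
        vals = np.unique(col[col >= 0])
        return vals

    # ------------------------------------------------------------------ groups
    def group_codes(self, by: str | Sequence[str]) -> tuple[np.ndarray, list]:
        """Integer group code per individual plus the ordered group keys.

        ``by`` is a label column or list of columns; multi-column groups are
        keyed by tuples. Groups are ordered by first appearance.
        """
        cols = [by] if isinstance(by, str) else list(by)
        for c in cols:
            if c not in self.labels.columns:
                raise KeyError(f"unknown label column {c!r}")
        if len(cols) == 1:
            keys_raw = self.labels[cols[0]].tolist()
        else:
            keys_raw = [tuple(r) for r in self.labels[cols].itertuples(index=False)]
        keys: list = []
        index: dict = {}
        codes = np.empty(len(keys_raw), dtype=np.int64)
        for i, k in enumerate(keys_raw):
            if k not in index:
                index[k] = len(keys)
                keys.append(k)
            codes[i] = index[k]
        return codes, keys

    def subset(self, mask: np.ndarray | Sequence[int]) -> "GroupedGenotypes":
        """Return a new container restricted to the selected individuals."""
        mask = np.asarray(mask)
        return GroupedGenotypes(
            self.calls[mask], self.loci, self.labels.iloc[np.atleast_1d(mask) if mask.dtype != bool else mask]
        )

    def select_groups(self, by: str | Sequence[str], groups: Iterable) -> "GroupedGenotypes":
        codes, keys = self.group_codes(by)
        wanted = {keys.index(g) for g in groups}
        mask = np.isin(codes, list(wanted))
        return self.subset(mask)

    # ------------------------------------------------------------------ builders
    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[Sequence[tuple[int, int] | None]],
        loci: Sequence[str] | None = None,
        labels: pd.DataFrame | dict | None = None,
    ) -> "GroupedGenotypes":
        """Build from nested python lists: ``pairs[i][l]`` is ``(a, b)`` or None."""
        n = len(pairs)
        n_loci = len(pairs[0]) if n else 0
        calls = np.full((n, n_loci, 2), MISSING, dtype=np.int64)
        for i, row in enumerate(pairs):
            for l, call in enumerate(row):
                if call is not None:
                    calls[i, l, 0], calls[i, l, 1] = call
        if loci is None:
            loci = [f"loc{l + 1}" for l in range(n_loci)]
        if labels is None:
            labels = pd.DataFrame(index=range(n))
        elif isinstance(labels, dict):
            labels = pd.DataFrame(labels)
        return cls(calls, loci, labels)

    @classmethod
    def from_dosage(
        cls,
        dosage_by_group: dict[str, np.ndarray],
        allele_codes: tuple[int, int] = (1, 2),
        group_column: str = "deme",
    ) -> "GroupedGenotypes":
        """Build from per-group diallelic dosage matrices.

        ``dosage_by_group[g]`` is an ``(n_g, n_loci)`` array counting copies of
        the first allele code; rows become individuals labelled ``g``.
        """
        a, b = allele_codes
        mats = {g: np.asarray(m) for g, m in dosage_by_group.items()}
        n_loci = next(iter(mats.values())).shape[1] if mats else 0
        blocks, labels, ids = [], [], []
        for g, m in mats.items():
            if m.size and m.shape[1] != n_loci:
                raise ValueError("inconsistent locus counts across groups")
            calls = np.empty((m.shape[0], n_loci, 2), dtype=np.int64)
            calls[:, :, 0] = np.where(m >= 1, a, b)
            calls[:, :, 1] = np.where(m == 2, a, b)
            blocks.append(calls)
            labels.extend([g] * m.shape[0])
            ids.extend(f"{g}_{i + 1}" for i in range(m.shape[0]))
        calls = (
            np.concatenate(blocks, axis=0)
            if blocks
            else np.empty((0, n_loci, 2), dtype=np.int64)
        )
        loci = [f"L{l + 1}" for l in range(n_loci)]
        return cls(calls, loci, pd.DataFrame({group_column: labels}, index=ids))

    # ------------------------------------------------------------------ misc
    def relabel_alleles(self, mapping: dict[int, int]) -> "GroupedGenotypes":
        """Return a copy with allele codes replaced via ``mapping`` (bijective)."""
        calls = self.calls.copy()
        out = calls.copy()
        for old, new in mapping.items():
            out[calls == old] = new
        return GroupedGenotypes(out, self.loci, self.labels)

    def reorder_loci(self, order: Sequence[int]) -> "GroupedGenotypes":
        return GroupedGenotypes(
            self.calls[:, list(order), :], [self.loci[i] for i in order], self.labels
        )

    def reorder_individuals(self, order: Sequence[int]) -> "GroupedGenotypes":
        return GroupedGenotypes(
            self.calls[list(order)], self.loci, self.labels.iloc[list(order)]
        )
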