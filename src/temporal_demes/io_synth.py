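"""Genotype file formats, allele cleaning, and synthetic data generation.

Formats
-------
* GenAlEx-like CSV: header rows carrying (n_loci, n_individuals, n_groups,
  group sizes), then two columns per locus; 0 encodes a missing allele.
* STRUCTURE text: tab-separated, two rows per individual (one per allele
  copy); -9 encodes missing.
* Arlequin ``.arp`` (write + read): [Profile]/[Data] sections, genotypic
  standard/microsat data with two allele lines per individual.

Cleaning
--------
Tetraploid-like raw calls (1-4 alleles per individual and marker) are
reduced to diploid calls by keeping, among the alleles an individual shows,
the two most common within its population; single-allele calls become
homozygotes. Ties break deterministically by the smaller allele code.

Synthesis
---------
Multi-allelic microsatellite-like data with controlled differentiation via
the Balding-Nichols model: per locus an ancestral frequency vector (uniform
Dirichlet) and per group a Dirichlet draw concentrated around it with
parameter (1 - theta)/theta, so that the expected F_ST equals theta.
Missing calls and supernumerary (3rd/4th) alleles are injected at
configurable rates emulating real microsatellite tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GroupedGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "read_genotype_table",
    "write_genotype_table",
    "write_arlequin",
    "read_arlequin",
    "clean_supernumerary_alleles",
    "generate_raw_calls",
    "generate_synthetic_microsat",
]


# ==================================================================== formats
class ParseError(ValueError):
    def __init__(self, msg: str, line: int | None = None):
        super().__init__(f"line {line}: {msg}" if line is not None else msg)
        self.line = line


def _group_join(labels: pd.DataFrame) -> list[str]:
    if labels.shape[1] == 0:
        return ["pop1"] * len(labels)
    return ["|".join(str(v) for v in row) for row in labels.itertuples(index=False)]


def write_genotype_table(
    data: GroupedGenotypes, path: str | Path, format: str = "genalex-csv"
) -> None:
    """Write a genotype table; see :func:`read_genotype_table` for dialects."""
    path = Path(path)
    groups = _group_join(data.labels)
    order = sorted(range(len(groups)), key=lambda i: (groups[i], i))
    if format == "genalex-csv":
        _write_genalex(data, path, groups, order)
    elif format == "structure-txt":
        _write_structure(data, path, groups, order)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_genalex(data, path, groups, order) -> None:
    keys = list(dict.fromkeys(groups[i] for i in order))
    sizes = [sum(1 for g in groups if g == k) for k in keys]
    lines = []
    lines.append(
        ",".join(
            str(v) for v in [data.n_loci, data.n_individuals, len(keys)] + sizes
        )
    )
    lines.append(",".join(["genotypes"] + keys))
    header = ["ind", "group"]
    for loc in data.loci:
        header += [loc, f"{loc}_2"]
    lines.append(",".join(header))
    for i in order:
        row = [str(data.labels.index[i]), groups[i]]
        for l in range(data.n_loci):
            a, b = data.calls[i, l]
            row += ["0", "0"] if a < 0 else [str(a), str(b)]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def _write_structure(data, path, groups, order) -> None:
    keys = list(dict.fromkeys(groups[i] for i in order))
    code = {k: j + 1 for j, k in enumerate(keys)}
    lines = ["\t".join(["ind", "pop"] + list(data.loci))]
    for i in order:
        for copy in range(2):
            row = [str(data.labels.index[i]), str(code[groups[i]])]
            for l in range(data.n_loci):
                a = data.calls[i, l, copy]
                row.append("-9" if a < 0 else str(a))
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_genotype_table(
    path: str | Path, format: str = "genalex-csv"
) -> GroupedGenotypes:
    """Parse a grouped genotype file (``genalex-csv`` or ``structure-txt``).

    Malformed input (ragged rows, undeclared loci, bad counts) raises
    :class:`ParseError` with the offending line number. Write -> read ->
    write round-trips are byte-identical.
    """
    path = Path(path)
    if format == "genalex-csv":
        return _read_genalex(path)
    if format == "structure-txt":
        return _read_structure(path)
    raise ValueError(f"unknown format {format!r}")


def _read_genalex(path: Path) -> GroupedGenotypes:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("file too short for the GenAlEx-like dialect")
    head = lines[0].split(",")
    try:
        n_loci, n_ind, n_groups = (int(x) for x in head[:3])
        sizes = [int(x) for x in head[3 : 3 + n_groups]]
    except (ValueError, IndexError):
        raise ParseError("bad numeric header", 1)
    if sum(sizes) != n_ind:
        raise ParseError("group sizes do not sum to individual count", 1)
    loci_row = lines[2].split(",")
    loci = loci_row[2::2]
    if len(loci) != n_loci:
        raise ParseError(
            f"header declares {n_loci} loci but {len(loci)} found", 3
        )
    ids, groups = [], []
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    body = lines[3 : 3 + n_ind]
    if len(body) != n_ind:
        raise ParseError(f"expected {n_ind} data rows, found {len(body)}")
    for r, line in enumerate(body):
        parts = line.split(",")
        if len(parts) != 2 + 2 * n_loci:
            raise ParseError("ragged row", 4 + r)
        ids.append(parts[0])
        groups.append(parts[1])
        for l in range(n_loci):
            try:
                a, b = int(parts[2 + 2 * l]), int(parts[3 + 2 * l])
            except ValueError:
                raise ParseError("non-integer allele", 4 + r)
            if a == 0 or b == 0:
                continue  # missing sentinel
            calls[r, l] = (a, b)
    return GroupedGenotypes(calls, loci, pd.DataFrame({"group": groups}, index=ids))


def _read_structure(path: Path) -> GroupedGenotypes:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("file too short for the STRUCTURE dialect")
    loci = lines[0].split("\t")[2:]
    n_loci = len(loci)
    body = lines[1:]
    if len(body) % 2:
        raise ParseError("odd number of allele rows (need two per individual)")
    n_ind = len(body) // 2
    ids, groups = [], []
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i in range(n_ind):
        rows = []
        for copy in range(2):
            ln = 2 + 2 * i + copy
            parts = body[2 * i + copy].split("\t")
            if len(parts) != 2 + n_loci:
                raise ParseError("ragged row", ln)
            rows.append(parts)
        if rows[0][0] != rows[1][0] or rows[0][1] != rows[1][1]:
            raise ParseError("allele-copy rows disagree on id/pop", 2 + 2 * i)
        ids.append(rows[0][0])
        groups.append(rows[0][1])
        for l in range(n_loci):
            try:
                a, b = int(rows[0][2 + l]), int(rows[1][2 + l])
            except ValueError:
                raise ParseError("non-integer allele", 2 + 2 * i)
            if a == -9 or b == -9:
                continue
            calls[i, l] = (a, b)
    return GroupedGenotypes(calls, loci, pd.DataFrame({"group": groups}, index=ids))


# --------------------------------------------------------------- Arlequin arp
def write_arlequin(
    data: GroupedGenotypes,
    path: str | Path,
    group_by: str | list[str] | None = None,
    title: str = "temporal_demes export",
    data_type: str = "MICROSAT",
) -> None:
    """Write a genotypic Arlequin ``.arp`` project (two allele lines per
    individual, '?' for missing)."""
    if data.n_individuals == 0:
        raise ValueError("empty genotype table")
    if group_by is None:
        groups = _group_join(data.labels)
    else:
        codes, keys = data.group_codes(group_by)
        groups = [str(keys[c]) for c in codes]
    keys = list(dict.fromkeys(groups))
    out = []
    out.append("[Profile]")
    out.append(f'  Title="{title}"')
    out.append(f"  NbSamples={len(keys)}")
    out.append(f"  DataType={data_type}")
    out.append("  GenotypicData=1")
    out.append("  GameticPhase=0")
    out.append("  MissingData='?'")
    out.append("")
    out.append("[Data]")
    out.append("  [[Samples]]")
    for k in keys:
        idx = [i for i, g in enumerate(groups) if g == k]
        out.append(f'    SampleName="{k}"')
        out.append(f"    SampleSize={len(idx)}")
        out.append("    SampleData= {")
        for i in idx:
            a_row, b_row = [], []
            for l in range(data.n_loci):
                a, b = data.calls[i, l]
                a_row.append("?" if a < 0 else str(a))
                b_row.append("?" if b < 0 else str(b))
            ident = str(data.labels.index[i])
            out.append(f"      {ident} 1 " + " ".join(a_row))
            out.append("      " + " " * (len(ident) + 3) + " ".join(b_row))
        out.append("    }")
    Path(path).write_text("\n".join(out) + "\n")


def read_arlequin(path: str | Path) -> GroupedGenotypes:
    """Parse a genotypic ``.arp`` written by :func:`write_arlequin`."""
    lines = Path(path).read_text().splitlines()
    samples: list[tuple[str, list[str], list[list[str]]]] = []
    i = 0
    name = None
    while i < len(lines):
        s = lines[i].strip()
        if s.startswith("SampleName="):
            name = s.split("=", 1)[1].strip().strip('"')
        elif s.startswith("SampleData="):
            i += 1
            ids, rows = [], []
            while i < len(lines) and lines[i].strip() != "}":
                first = lines[i].strip().split()
                second = lines[i + 1].strip().split()
                if len(first) < 3:
                    raise ParseError("malformed sample row", i + 1)
                ids.append(first[0])
                rows.append([first[2:], second])
                i += 2
            samples.append((name, ids, rows))
        i += 1
    if not samples:
        raise ParseError("no [[Samples]] blocks found")
    n_loci = len(samples[0][2][0][0])
    all_ids, all_groups, all_calls = [], [], []
    for name, ids, rows in samples:
        for ident, (a_row, b_row) in zip(ids, rows):
            if len(a_row) != n_loci or len(b_row) != n_loci:
                raise ParseError(f"inconsistent locus count for {ident}")
            call = np.full((n_loci, 2), MISSING, dtype=np.int64)
            for l, (a, b) in enumerate(zip(a_row, b_row)):
                if a != "?" and b != "?":
                    call[l] = (int(a), int(b))
            all_ids.append(ident)
            all_groups.append(name)
            all_calls.append(call)
    calls = np.stack(all_calls)
    loci = [f"L{l + 1}" for l in range(n_loci)]
    return GroupedGenotypes(
        calls, loci, pd.DataFrame({"group": all_groups}, index=all_ids)
    )


# =================================================================== cleaning
RawCalls = list  # raw[i][l] -> tuple/list of 1-4 allele codes, or None


def clean_supernumerary_alleles(
    raw: RawCalls,
    populations: list,
    loci: list[str] | None = None,
    labels: pd.DataFrame | None = None,
    include_focal: bool = True,
) -> GroupedGenotypes:
    """Reduce raw 1-4 allele calls to diploid calls.

    For an individual showing more than two alleles at a marker, the two
    with the highest frequency within that individual's population (counting
    each allele once per individual listing it) are kept; equal frequencies
    break towards the smaller allele code (logged). Single-allele calls
    become homozygotes; two-allele calls pass through unchanged.
    ``include_focal=False`` excludes the focal individual's own listing from
    the frequency counts.
    """
    n = len(raw)
    n_loci = len(raw[0]) if n else 0
    if loci is None:
        loci = [f"loc{l + 1}" for l in range(n_loci)]
    pops = list(populations)
    # population x locus allele counts
    counts: dict[tuple, dict[int, int]] = {}
    for i in range(n):
        for l in range(n_loci):
            call = raw[i][l]
            if not call:
                continue
            d = counts.setdefault((pops[i], l), {})
            for a in set(call):
                d[a] = d.get(a, 0) + 1
    calls = np.full((n, n_loci, 2), MISSING, dtype=np.int64)
    for i in range(n):
        for l in range(n_loci):
            call = raw[i][l]
            if not call:
                continue
            obs = sorted(set(call))
            if len(obs) == 1:
                calls[i, l] = (obs[0], obs[0])
                continue
            if len(obs) == 2:
                calls[i, l] = (obs[0], obs[1])
                continue
            d = counts[(pops[i], l)]
            freq = {a: d.get(a, 0) for a in obs}
            if not include_focal:
                freq = {a: freq[a] - 1 for a in obs}
            ranked = sorted(obs, key=lambda a: (-freq[a], a))
            if freq[ranked[1]] == freq[ranked[2]]:
                logger.info(
                    "tie among alleles %s at locus %s (individual %d); "
                    "kept smaller code",
                    obs,
                    loci[l],
                    i,
                )
            keep = sorted(ranked[:2])
            calls[i, l] = (keep[0], keep[1])
    if labels is None:
        labels = pd.DataFrame({"population": pops})
    return GroupedGenotypes(calls, loci, labels)


# ================================================================== synthesis
@dataclass
class SyntheticSpec:
    """Recipe for Balding-Nichols microsatellite-like data.

    ``theta`` is the target differentiation among groups; ``missing_rate``
    and ``supernumerary_rate`` emulate the blemishes of real microsatellite
    tables (defaults follow the empirical dataset the generator imitates:
    3.4% missing calls, ~1% calls with 3-4 alleles).
    """

    n_groups: int = 2
    n_per_group: int = 50
    n_loci: int = 9
    n_alleles: int = 10
    theta: float = 0.05
    missing_rate: float = 0.034
    supernumerary_rate: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        for nm in ("missing_rate", "supernumerary_rate"):
            if not 0.0 <= getattr(self, nm) <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")


def generate_raw_calls(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[RawCalls, list]:
    """Raw (possibly supernumerary / missing) calls plus population labels."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_groups * spec.n_per_group
    pops = [f"pop{g + 1}" for g in range(spec.n_groups) for _ in range(spec.n_per_group)]
    # microsatellite-style allele codes (fragment sizes)
    codes = 100 + 2 * np.arange(spec.n_alleles)
    raw: RawCalls = [[None] * spec.n_loci for _ in range(n)]
    for l in range(spec.n_loci):
        ancestral = rng.dirichlet(np.ones(spec.n_alleles))
        conc = (1.0 - spec.theta) / spec.theta
        for g in range(spec.n_groups):
            p = rng.dirichlet(ancestral * conc)
            block = slice(g * spec.n_per_group, (g + 1) * spec.n_per_group)
            draws = rng.choice(spec.n_alleles, size=(spec.n_per_group, 2), p=p)
            for j, i in enumerate(range(*block.indices(n))):
                if rng.random() < spec.missing_rate:
                    continue
                alleles = [int(codes[a]) for a in draws[j]]
                if rng.random() < spec.supernumerary_rate:
                    extra = rng.choice(spec.n_alleles, size=rng.integers(1, 3), p=p)
                    alleles += [int(codes[a]) for a in extra]
                raw[i][l] = tuple(alleles)
    return raw, pops


def generate_synthetic_microsat(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> GroupedGenotypes:
    """Synthetic grouped microsatellite genotypes (cleaned to diploid calls
    via the two-most-common-alleles rule). Deterministic given the seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    raw, pops = generate_raw_calls(spec, rng)
    ids = [f"ind{i + 1}" for i in range(len(raw))]
    labels = pd.DataFrame({"population": pops}, index=ids)
    return clean_supernumerary_alleles(raw, pops, labels=labels)
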