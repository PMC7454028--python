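"""Independent brute-force oracles used by the test-suite.

These deliberately take the slow, definitional route (double loops over
pairs of allele copies) so that agreement with the package's sums-of-squares
implementation is a genuine cross-check, not a reimplementation.
"""

from __future__ import annotations

import numpy as np

from temporal_demes import GroupedGenotypes


def amova_components_oracle(
    data: GroupedGenotypes, group_by: str
) -> list[tuple[float, float, float]]:
    """Per-locus (sigma_a, sigma_b, sigma_c) from pairwise squared Euclidean
    distances between one-hot-coded allele copies (d^2 = 2 for unlike
    alleles), with the unbalanced nested-ANOVA expected-mean-square solve
    done from the textbook formulas.
    """
    codes, keys = data.group_codes(group_by)
    P = len(keys)
    out = []
    for l in range(data.n_loci):
        copies = []  # (group, individual, allele)
        for i in range(data.n_individuals):
            a, b = data.calls[i, l]
            if a < 0:
                continue
            copies.append((codes[i], i, a))
            copies.append((codes[i], i, b))
        inds = sorted({c[1] for c in copies})
        N = len(inds)
        groups = sorted({c[0] for c in copies})
        if N < 2 or len(groups) < 2:
            out.append((np.nan, np.nan, np.nan))
            continue

        def d2(x, y):
            return 0.0 if x == y else 2.0

        def ss(subset):
            n = len(subset)
            tot = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    tot += d2(subset[i][2], subset[j][2])
            return tot / n if n else 0.0

        ss_total = ss(copies)
        ss_groups = sum(ss([c for c in copies if c[0] == g]) for g in groups)
        ss_inds = sum(ss([c for c in copies if c[1] == i]) for i in inds)
        ss_ag = ss_total - ss_groups
        ss_ai = ss_groups - ss_inds
        ss_wi = ss_inds

        n_g = {g: len({c[1] for c in copies if c[0] == g}) for g in groups}
        Pl = len(groups)
        sig_c = ss_wi / N
        sig_b = (ss_ai / (N - Pl) - sig_c) / 2.0 if N > Pl else np.nan
        n_c = (N - sum(v**2 for v in n_g.values()) / N) / (Pl - 1)
        sig_a = (
            (ss_ag / (Pl - 1) - sig_c - 2.0 * sig_b) / (2.0 * n_c)
            if n_c > 0
            else np.nan
        )
        out.append((sig_a, sig_b, sig_c))
    return out


def fst_oracle(data: GroupedGenotypes, group_by: str) -> float:
    comps = amova_components_oracle(data, group_by)
    arr = np.array(comps, dtype=float)
    ok = np.isfinite(arr).all(axis=1)
    a, b, c = arr[ok].sum(axis=0)
    return a / (a + b + c)


def centroid_distance_oracle(model, group_a, group_b) -> float:
    """Naive mean-and-norm: average the per-individual discriminant
    coordinates of each group, then take the Euclidean norm of the
    difference."""
    in_a = np.array([lab == group_a for lab in model.labels])
    in_b = np.array([lab == group_b for lab in model.labels])
    ca = model.coords[in_a].mean(axis=0)
    cb = model.coords[in_b].mean(axis=0)
    return float(np.sqrt(((ca - cb) ** 2).sum()))
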