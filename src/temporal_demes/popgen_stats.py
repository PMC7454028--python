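"""Population-genetic statistics on grouped co-dominant genotypes.

Implements, from variance components:

* Nei diversity summaries (n_a, H_O, unbiased H_S) per group;
* two-level AMOVA F_ST for genotypic data (among groups / among individuals
  within groups / within individuals) with a permutation test on group
  membership;
* hierarchical F-statistics for arbitrarily nested label hierarchies with a
  bootstrap over loci for confidence intervals.

The variance components follow the Excoffier/Cockerham analysis-of-variance
framework: at every locus each allele is treated as a 0/1 indicator on the
2N allele copies, sums of squares are computed at each nesting level, and the
components are obtained from the expected-mean-square equations of the
unbalanced nested random model. Multi-locus F-statistics are ratios of
components summed over loci (not means of per-locus ratios). Missing calls
are excluded locus-wise; negative components are reported raw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GroupedGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "DiversitySummary",
    "AmovaResult",
    "HierFResult",
    "diversity_summary",
    "amova_fst",
    "pairwise_fst",
    "hierarchical_f",
]


# ===================================================================== dosage
class _Dosage:
    """Per-(locus, allele) dosage expansion of a genotype table.

    ``D[i, k]`` counts copies of allele ``k`` (a (locus, allele) column) in
    individual ``i`` (0 where the call is missing); ``S[i, l]`` flags scored
    calls. Columns of one locus are contiguous.
    """

    def __init__(self, data: GroupedGenotypes):
        n, L = data.n_individuals, data.n_loci
        scored = data.scored_mask()
        cols: list[np.ndarray] = []
        col_locus: list[int] = []
        starts: list[int] = []
        alleles: list[np.ndarray] = []
        for l in range(L):
            al = data.alleles(l)
            alleles.append(al)
            starts.append(len(col_locus))
            pair = data.calls[:, l, :]
            for a in al:
                d = (pair == a).sum(axis=1).astype(np.float64)
                d[~scored[:, l]] = 0.0
                cols.append(d)
                col_locus.append(l)
        self.D = np.column_stack(cols) if cols else np.empty((n, 0))
        self.S = scored.astype(np.float64)
        self.col_locus = np.asarray(col_locus, dtype=np.int64)
        self.locus_starts = np.asarray(starts, dtype=np.int64)
        self.alleles = alleles
        self.n_loci = L
        self.n_individuals = n
        # group-independent pieces
        self.T_obs = self.D.sum(axis=0)
        self.T_ind = (self.D**2).sum(axis=0) / 2.0
        self.N_l = self.S.sum(axis=0)  # scored individuals per locus
        with np.errstate(divide="ignore", invalid="ignore"):
            self.T_tot = np.where(
                self.N_l[self.col_locus] > 0,
                self.T_obs**2 / (2.0 * self.N_l[self.col_locus]),
                0.0,
            )
        self.SS_wi = self._per_locus(self.T_obs - self.T_ind)

    def _per_locus(self, per_col: np.ndarray) -> np.ndarray:
        """Sum a per-column quantity over the columns of each locus."""
        if per_col.size == 0:
            return np.zeros(self.n_loci)
        out = np.add.reduceat(per_col, self.locus_starts)
        # reduceat misbehaves for loci with zero columns; impossible here
        return out


def _one_hot(codes: np.ndarray, P: int) -> np.ndarray:
    M = np.zeros((P, codes.size))
    M[codes, np.arange(codes.size)] = 1.0
    return M


def _two_level_components(
    dos: _Dosage, codes: np.ndarray, P: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (sigma_a, sigma_b, sigma_c).

    sigma_a: among groups, sigma_b: among individuals within groups,
    sigma_c: within individuals. Loci where the design is degenerate
    (fewer than two groups scored, or no within-group replication) come
    back as NaN.
    """
    M = _one_hot(codes, P)
    GS = M @ dos.D  # (P, K) group dosage sums
    n_gl = M @ dos.S  # (P, L) scored individuals per group x locus
    with np.errstate(divide="ignore", invalid="ignore"):
        t_grp_cols = np.where(
            n_gl[:, dos.col_locus] > 0, GS**2 / (2.0 * n_gl[:, dos.col_locus]), 0.0
        ).sum(axis=0)
    SS_ag = dos._per_locus(t_grp_cols - dos.T_tot)
    SS_ai = dos._per_locus(dos.T_ind - t_grp_cols)

    N_l = dos.N_l
    P_l = (n_gl > 0).sum(axis=0).astype(np.float64)
    df_ag = P_l - 1.0
    df_ai = N_l - P_l
    with np.errstate(divide="ignore", invalid="ignore"):
        sig_c = np.where(N_l > 0, dos.SS_wi / N_l, np.nan)
        sig_b = np.where(df_ai > 0, (SS_ai / df_ai - sig_c) / 2.0, np.nan)
        n_c = np.where(
            (df_ag > 0) & (N_l > 0),
            (N_l - (n_gl**2).sum(axis=0) / np.where(N_l > 0, N_l, 1.0)) / df_ag,
            np.nan,
        )
        sig_a = np.where(
            (df_ag > 0) & (n_c > 0),
            (SS_ag / df_ag - sig_c - 2.0 * sig_b) / (2.0 * n_c),
            np.nan,
        )
    return sig_a, sig_b, sig_c


def _multilocus_f(sig_a, sig_b, sig_c) -> float:
    valid = np.isfinite(sig_a) & np.isfinite(sig_b) & np.isfinite(sig_c)
    if not valid.any():
        return np.nan
    a, b, c = sig_a[valid].sum(), sig_b[valid].sum(), sig_c[valid].sum()
    tot = a + b + c
    return a / tot if tot != 0 else np.nan


# ====================================================================== AMOVA
@dataclass
class AmovaResult:
    """Two-level AMOVA of genotypic data.

    ``levels`` rows: among groups / among individuals within groups / within
    individuals, with design df, variance component and percent of variation
    (components reported raw; negative estimates are possible and meaningful
    as sampling noise around zero).
    """

    levels: pd.DataFrame
    fst: float
    fis: float
    fit: float
    p_fst: float | None
    n_permutations: int
    n_groups: int
    n_individuals: int
    per_locus: pd.DataFrame

    @property
    def monomorphic(self) -> bool:
        return not np.isfinite(self.fst)

    def to_frame(self) -> pd.DataFrame:
        out = self.levels.copy()
        out["fixation_index"] = [self.fst, self.fis, self.fit]
        out["p_value"] = [self.p_fst, None, None]
        return out


def _check_groups(codes: np.ndarray, keys: list, min_size: int = 2) -> None:
    if len(keys) < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes, minlength=len(keys))
    small = [keys[i] for i in np.nonzero(sizes < min_size)[0]]
    if small:
        raise ValueError(f"groups with fewer than {min_size} individuals: {small}")


def amova_fst(
    data: GroupedGenotypes,
    group_by: str | list[str] = "deme",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """Two-level AMOVA F_ST with a permutation test.

    The permutation unit is the individual (both allele copies move
    together): group labels are reshuffled ``n_perm`` times preserving group
    sizes, and ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    codes, keys = data.group_codes(group_by)
    _check_groups(codes, keys)
    P = len(keys)
    dos = _Dosage(data)
    sig_a, sig_b, sig_c = _two_level_components(dos, codes, P)
    fst = _multilocus_f(sig_a, sig_b, sig_c)

    valid = np.isfinite(sig_a) & np.isfinite(sig_b) & np.isfinite(sig_c)
    a = sig_a[valid].sum() if valid.any() else np.nan
    b = sig_b[valid].sum() if valid.any() else np.nan
    c = sig_c[valid].sum() if valid.any() else np.nan
    tot = a + b + c
    if not np.isfinite(fst):
        logger.warning("monomorphic dataset: F_ST undefined (NaN)")
    fis = b / (b + c) if (b + c) != 0 else np.nan
    fit = (a + b) / tot if tot != 0 else np.nan

    n = data.n_individuals
    levels = pd.DataFrame(
        {
            "level": [
                "among_groups",
                "among_individuals_within_groups",
                "within_individuals",
            ],
            "df": [P - 1, n - P, n],
            "sigma2": [a, b, c],
            "percent": [100 * a / tot, 100 * b / tot, 100 * c / tot]
            if tot != 0
            else [np.nan] * 3,
        }
    )

    p_val: float | None = None
    if n_perm > 0 and np.isfinite(fst):
        if rng is None:
            rng = np.random.default_rng()
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            f = _multilocus_f(*_two_level_components(dos, perm, P))
            if np.isfinite(f) and f >= fst - 1e-12:
                hits += 1
        p_val = (1 + hits) / (1 + n_perm)

    per_locus = pd.DataFrame(
        {"locus": data.loci, "sigma_a": sig_a, "sigma_b": sig_b, "sigma_c": sig_c}
    )
    return AmovaResult(
        levels=levels,
        fst=float(fst),
        fis=float(fis),
        fit=float(fit),
        p_fst=p_val,
        n_permutations=n_perm,
        n_groups=P,
        n_individuals=n,
        per_locus=per_locus,
    )


def pairwise_fst(
    data: GroupedGenotypes,
    group_a,
    group_b,
    group_by: str | list[str] = "deme",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """AMOVA F_ST restricted to two groups; symmetric in argument order."""
    sub = data.select_groups(group_by, sorted({group_a, group_b}, key=repr))
    res = amova_fst(sub, group_by=group_by, n_perm=n_perm, rng=rng)
    return res.fst, res.p_fst


# ================================================================== diversity
@dataclass
class DiversitySummary:
    """Per-group diversity: mean alleles per locus (n_a), observed
    heterozygosity (H_O) and Nei's unbiased gene diversity (H_S), each with
    the SD across loci; ``per_locus`` carries the locus-level values."""

    per_group: pd.DataFrame
    per_locus: pd.DataFrame

    def overall(self, weight_by_loci: bool = False) -> pd.Series:
        """Mean of the group means, unweighted or weighted by the number of
        scored loci per group (both reported because grouped data with
        missing loci admit either convention)."""
        g = self.per_group
        if weight_by_loci:
            w = g["n_loci_scored"].to_numpy(dtype=float)
            w = w / w.sum()
            vals = {c: float((g[c] * w).sum()) for c in ("n_a", "H_O", "H_S")}
        else:
            vals = {c: float(g[c].mean()) for c in ("n_a", "H_O", "H_S")}
        vals.update({f"{c}_sd": float(g[c].std(ddof=1)) for c in ("n_a", "H_O", "H_S")})
        return pd.Series(vals)


def diversity_summary(
    data: GroupedGenotypes, group_by: str | list[str]
) -> DiversitySummary:
    """Diversity indices per group.

    n_a: distinct alleles per locus; H_O: fraction of heterozygous scored
    individuals; H_S: (2n/(2n-1)) (1 - sum p_i^2). Loci with no scored call
    in a group are excluded from that group's means (warning logged).
    """
    codes, keys = data.group_codes(group_by)
    if len(keys) < 1:
        raise ValueError("no groups")
    rows_l, rows_g = [], []
    for gi, key in enumerate(keys):
        sub = data.calls[codes == gi]
        if sub.shape[0] == 0:
            raise ValueError(f"empty group {key!r}")
        scored_any = False
        na_l, ho_l, hs_l, loci_used = [], [], [], []
        for l, locus in enumerate(data.loci):
            pair = sub[:, l, :]
            ok = pair[:, 0] >= 0
            n = int(ok.sum())
            if n == 0:
                logger.warning("group %r: locus %s has no scored calls", key, locus)
                continue
            scored_any = True
            obs = pair[ok]
            alleles, counts = np.unique(obs.ravel(), return_counts=True)
            p = counts / (2.0 * n)
            het = float((obs[:, 0] != obs[:, 1]).mean())
            hs = 1.0 - float((p**2).sum())
            if 2 * n > 1:
                hs *= (2.0 * n) / (2.0 * n - 1.0)
            na_l.append(len(alleles))
            ho_l.append(het)
            hs_l.append(hs)
            loci_used.append(locus)
            rows_l.append(
                {
                    "group": key,
                    "locus": locus,
                    "n": n,
                    "n_a": len(alleles),
                    "H_O": het,
                    "H_S": hs,
                }
            )
        if not scored_any:
            raise ValueError(f"group {key!r} has no scored genotypes")
        na, ho, hs = map(np.asarray, (na_l, ho_l, hs_l))
        rows_g.append(
            {
                "group": key,
                "n_individuals": int(sub.shape[0]),
                "n_loci_scored": len(loci_used),
                "n_a": float(na.mean()),
                "n_a_sd": float(na.std(ddof=1)) if na.size > 1 else np.nan,
                "H_O": float(ho.mean()),
                "H_O_sd": float(ho.std(ddof=1)) if ho.size > 1 else np.nan,
                "H_S": float(hs.mean()),
                "H_S_sd": float(hs.std(ddof=1)) if hs.size > 1 else np.nan,
            }
        )
    return DiversitySummary(
        per_group=pd.DataFrame(rows_g).set_index("group"),
        per_locus=pd.DataFrame(rows_l),
    )


# ========================================================== hierarchical F
@dataclass
class HierFResult:
    """Hierarchical F-statistics with bootstrap-over-loci CIs.

    ``levels``: one row per hierarchy level (plus the individual level),
    F relative to total, 2.5-97.5% CI (None when unavailable) and a
    significance flag (CI excludes zero)."""

    levels: pd.DataFrame
    n_bootstraps: int
    per_locus_components: pd.DataFrame  # one sigma^2 column per level + residual


def _nested_codes(
    data: GroupedGenotypes, hierarchy: list[str]
) -> list[np.ndarray]:
    """Cumulative (hence nested) integer codes for each hierarchy depth."""
    out = []
    for i in range(len(hierarchy)):
        codes, _ = data.group_codes(hierarchy[: i + 1])
        out.append(codes)
    return out


def _k_coef(child_sizes: np.ndarray, child_parent: np.ndarray,
            parent_sizes: np.ndarray) -> float:
    """k(P, Q) = sum_g sum_{c in g} n_c^2 / n_g for nested partitions
    (sizes in allele copies; Q finer than P, ``child_parent`` maps Q-cells
    to their containing P-cell)."""
    num = np.bincount(child_parent, weights=child_sizes**2,
                      minlength=parent_sizes.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(parent_sizes > 0, num / parent_sizes, 0.0)
    return float(terms.sum())


def _locus_components(
    calls_l: np.ndarray, level_codes: list[np.ndarray]
) -> np.ndarray | None:
    """Variance components at one locus for the nested hierarchy.

    ``level_codes``: codes per individual for each labelled level (top to
    bottom). Returns sigma^2 for [level_1, ..., level_L, individual,
    within-individual], or None when degenerate (unsolvable design).
    """
    ok = calls_l[:, 0] >= 0
    n = int(ok.sum())
    if n < 2:
        return None
    obs = calls_l[ok]
    L = len(level_codes)
    # partitions over scored individuals: total, levels, individual
    parts: list[np.ndarray] = [np.zeros(n, dtype=np.int64)]
    for c in level_codes:
        parts.append(pd.factorize(c[ok])[0].astype(np.int64))
    parts.append(np.arange(n, dtype=np.int64))
    n_parts = len(parts)  # = L + 2 (total..individual)

    sizes = [np.bincount(p).astype(np.float64) * 2.0 for p in parts]  # copies

    alleles = np.unique(obs.ravel())
    # T(P) per partition, summed over alleles; T_obs for the copy level
    T = np.zeros(n_parts)
    T_obs = 0.0
    for a in alleles:
        d = (obs == a).sum(axis=1).astype(np.float64)
        T_obs += d.sum()
        for pi, p in enumerate(parts):
            gs = np.bincount(p, weights=d)
            T[pi] += float((gs**2 / sizes[pi]).sum())

    R = L + 2  # components: levels 1..L, individual, copy
    SS = np.empty(R)
    for i in range(1, n_parts):  # SS for partitions levels..individual
        SS[i - 1] = T[i] - T[i - 1]
    SS[R - 1] = T_obs - T[-1]  # within individuals

    # parent maps between consecutive partitions (first-occurrence based)
    def parent_map(child: np.ndarray, parent: np.ndarray) -> np.ndarray:
        m = np.zeros(int(child.max()) + 1, dtype=np.int64)
        m[child] = parent
        return m

    # k(P_i, Q_m) for partitions P_i (index 0..n_parts-1 over
    # total..individual) and components m (levels, individual, copy)
    K = np.zeros((n_parts, R))
    for pi in range(n_parts):
        for m in range(R - 1):  # labelled levels + individual -> partition m+1
            qi = m + 1
            if qi <= pi:
                # component partition coarser than or equal to P_i:
                # every g in P_i lies inside one Q-cell, so k = total copies
                K[pi, m] = 2.0 * n
            else:
                # map cells of the finer partition qi to their P_i parent
                par = parts[pi]
                child = parts[qi]
                cp = np.zeros(int(child.max()) + 1, dtype=np.int64)
                cp[child] = par
                K[pi, m] = _k_coef(sizes[qi], cp, sizes[pi])
        K[pi, R - 1] = float(len(sizes[pi]))  # copy component: one per cell
    # rows of the EMS system: differences of consecutive partitions, plus WI
    C = np.zeros((R, R))
    for i in range(1, n_parts):
        C[i - 1] = K[i] - K[i - 1]
    # within-individual row: k(copies, m) - k(individual, m)
    k_obs = np.full(R, 2.0 * n)
    C[R - 1] = k_obs - K[-1]

    df = np.array(
        [len(sizes[i]) - len(sizes[i - 1]) for i in range(1, n_parts)] + [n],
        dtype=float,
    )
    active = df > 0
    sig = np.zeros(R)
    try:
        sub = np.linalg.solve(C[np.ix_(active, active)], SS[active])
    except np.linalg.LinAlgError:
        return None
    sig[active] = sub
    return sig


def hierarchical_f(
    data: GroupedGenotypes,
    hierarchy: list[str],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> HierFResult:
    """Hierarchical F-statistics for a nested label hierarchy.

    ``hierarchy`` lists label columns from the broadest level downward;
    individuals form an implicit final level. For each level i the statistic
    F_{i/total} = (sum of components down to level i) / (total variance) is
    reported, components being summed over loci. A two-entry hierarchy of one
    grouping column reproduces :func:`amova_fst`'s F_ST exactly. CIs are
    percentile bootstrap over loci; a level is significant when its CI
    excludes zero.
    """
    if not hierarchy:
        raise ValueError("hierarchy must name at least one label column")
    level_codes = _nested_codes(data, hierarchy)
    for i in range(1, len(level_codes)):
        # cumulative codes are nested by construction; nothing to validate
        pass
    R = len(hierarchy) + 2
    comps = []
    kept_loci = []
    for l, locus in enumerate(data.loci):
        sig = _locus_components(data.calls[:, l, :], level_codes)
        if sig is not None and np.all(np.isfinite(sig)):
            comps.append(sig)
            kept_loci.append(locus)
    if not comps:
        raise ValueError("no usable loci for hierarchical F-statistics")
    comp = np.asarray(comps)  # (L_valid, R)

    level_names = list(hierarchy) + ["individual"]

    def f_ratios(c: np.ndarray) -> np.ndarray:
        s = c.sum(axis=0)
        tot = s.sum()
        if tot == 0:
            return np.full(R - 1, np.nan)
        return np.cumsum(s)[:-1] / tot

    point = f_ratios(comp)

    ci_lo = [None] * (R - 1)
    ci_hi = [None] * (R - 1)
    signif = [None] * (R - 1)
    if n_boot > 0 and comp.shape[0] > 1:
        if rng is None:
            rng = np.random.default_rng()
        boots = np.empty((n_boot, R - 1))
        Lv = comp.shape[0]
        for b in range(n_boot):
            idx = rng.integers(0, Lv, size=Lv)
            boots[b] = f_ratios(comp[idx])
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
        ci_lo, ci_hi = lo.tolist(), hi.tolist()
        signif = [(l > 0) or (h < 0) for l, h in zip(lo, hi)]
    elif n_boot > 0:
        warnings.warn("single usable locus: bootstrap CI unavailable")

    levels = pd.DataFrame(
        {
            "level": [f"{name}/total" for name in level_names],
            "f": point,
            "ci_low": ci_lo,
            "ci_high": ci_hi,
            "significant": signif,
        }
    )
    cols = [f"sigma2_{n}" for n in level_names] + ["sigma2_within_individual"]
    per_locus = pd.DataFrame(comp, columns=cols)
    per_locus.insert(0, "locus", kept_loci)
    return HierFResult(levels=levels, n_bootstraps=n_boot, per_locus_components=per_locus)
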