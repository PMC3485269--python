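"""Differential cluster detection and seven-way inheritance classification.

A one-way fixed-effects ANOVA over three genotype groups (the two inbred
parents and a hybrid group) flags differentially expressed (DE) clusters at
a Benjamini-Hochberg FDR of 5%.  Each DE cluster is then classified into one
of seven inheritance patterns by a small decision tree of t-tests at
alpha = 0.05 together with the dominance-to-additivity statistic

    a  = (high parent - low parent) / 2      (additive half-range)
    d  = hybrid - midparent                  (dominance deviation)
    d/a = 1  -> hybrid at the high parent
    d/a = -1 -> hybrid at the low parent
    d/a = 0  -> additive (midparent) inheritance

For the reciprocal hybrids a parent-of-origin variant uses
a' = (paternal - maternal) / 2, so d/a' = +1 means the hybrid tracks the
paternal parent.

Three analysis sets are supported: set I pools both reciprocal hybrids into
one group; sets II and III use one reciprocal each (LC = L maternal x C
paternal, and CL respectively), which also gives them a defined
parent-of-origin for d/a'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ClusterCountMatrix, bio_sample_id, validate_design

PATTERNS = (
    "additive",        # mid-parent like (MP)
    "HP",              # high parent like
    "LP",              # low parent like
    "AHP",             # above high parent
    "BLP",             # below low parent
    "between_MP_HP",
    "between_MP_LP",
)

NON_ADDITIVE = tuple(p for p in PATTERNS if p != "additive")

DEFAULT_FDR = 0.05
DEFAULT_ALPHA = 0.05

#: Hybrid genotypes entering the hybrid group of each analysis set, plus the
#: (maternal, paternal) parent identity where parent-of-origin is defined.
ANALYSIS_SETS = {
    "I": {"hybrids": ("CL", "LC"), "parent_of_origin": None},
    "II": {"hybrids": ("LC",), "parent_of_origin": ("LL", "CC")},
    "III": {"hybrids": ("CL",), "parent_of_origin": ("CC", "LL")},
}


def group_columns(design: pd.DataFrame, set_id: str) -> dict[str, list[str]]:
    """Biological-sample columns of the CC, LL and hybrid groups of a set."""
    if set_id not in ANALYSIS_SETS:
        raise ValueError(f"unknown analysis set {set_id!r}; expected I, II or III")
    validate_design(design)
    bio = design[["genotype", "bio_rep"]].drop_duplicates()
    cols = {
        gt: [bio_sample_id(gt, b) for b in sorted(bio[bio["genotype"] == gt]["bio_rep"])]
        for gt in ("CC", "LL", "CL", "LC")
    }
    hybrid = [c for gt in ANALYSIS_SETS[set_id]["hybrids"] for c in cols[gt]]
    groups = {"CC": cols["CC"], "LL": cols["LL"], "H": hybrid}
    for name, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {name} has fewer than 2 biological replicates")
    return groups


# ---------------------------------------------------------------------------
# ANOVA + FDR gate
# ---------------------------------------------------------------------------

def anova_oneway(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise classical one-way fixed-effects ANOVA.

    Each element of ``groups`` is an (n_clusters, n_i) array.  Returns
    (F, p) per row.  Degenerate rows with zero within-group variance get
    p = 1 when the group means are also equal and p = 0 otherwise.
    """
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n_total = ns.sum()
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = np.column_stack([g.sum(axis=1) for g in groups]).sum(axis=1) / n_total
    ss_between = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.column_stack(
        [((g - means[:, [i]]) ** 2).sum(axis=1) for i, g in enumerate(groups)]
    ).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(f, df_b, df_w)
    degenerate = ss_within <= 0
    equal_means = ss_between <= 1e-12 * np.maximum(grand, 1.0) ** 2
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    f = np.where(degenerate, np.inf, f)
    f = np.where(degenerate & equal_means, 0.0, f)
    return f, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def anova_de(
    matrix: ClusterCountMatrix,
    design: pd.DataFrame,
    set_id: str = "I",
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """ANOVA + BH gate over a filtered cluster count matrix.

    Returns a frame indexed by cluster_id with columns ``F, p, q, is_de``.
    """
    if matrix.stage != "filtered":
        raise ValueError(f"expected filtered matrix, got {matrix.stage}")
    groups = group_columns(design, set_id)
    arrays = [matrix.values[cols].to_numpy(float) for cols in groups.values()]
    f, p = anova_oneway(arrays)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"F": f, "p": p, "q": q, "is_de": q <= fdr}, index=matrix.values.index
    )


def null_fdp_calibration(
    seed: int,
    n_clusters: int = 1000,
    repeats: int = 2000,
    mean: float = 50.0,
    dispersion: float = 0.1,
    group_sizes: tuple[int, int, int] = (3, 3, 4),
    fdr: float = DEFAULT_FDR,
) -> dict[str, float]:
    """Simulated calibration of the ANOVA + BH gate under a complete null.

    Each repeat draws ``n_clusters`` clusters whose three genotype groups
    share one negative-binomial distribution (``Var = mean + dispersion *
    mean^2``), runs the gate, and records the false-discovery proportion
    (V / max(R, 1); every discovery is false under the complete null) and
    the fraction of clusters rejected.  Returns the means over repeats.

    Note the per-repeat FDP is a Bernoulli indicator under the complete
    null, so the Monte-Carlo standard error of ``mean_fdp`` is roughly
    ``sqrt(fdr / repeats)``; use enough repeats for the precision needed.
    """
    from .simulate import nb_counts  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rows = []
    for gt, n in zip(("CC", "LL", "CL"), group_sizes):
        for b in range(1, n + 1):
            rows.append(
                {"library_id": f"{gt}_b{b}_t1", "genotype": gt, "bio_rep": b,
                 "tech_rep": 1, "total_mapped_reads": 1_000_000}
            )
    design = pd.DataFrame(rows)
    cols = [bio_sample_id(r["genotype"], r["bio_rep"]) for r in rows]
    fdps, fractions = [], []
    for _ in range(repeats):
        counts = nb_counts(rng, np.full((n_clusters, len(cols)), mean), dispersion)
        matrix = ClusterCountMatrix(
            values=pd.DataFrame(
                counts.astype(float), columns=cols,
                index=[f"null{i}" for i in range(n_clusters)],
            ),
            stage="filtered",
        )
        de = anova_de(matrix, design, set_id="III", fdr=fdr)
        rejected = int(de["is_de"].sum())
        fdps.append(rejected / max(rejected, 1))
        fractions.append(rejected / n_clusters)
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_rejected_fraction": float(np.mean(fractions)),
        "repeats": repeats,
        "n_clusters": n_clusters,
    }


# ---------------------------------------------------------------------------
# d/a statistics
# ---------------------------------------------------------------------------

def compute_da(mean_cc: float, mean_ll: float, mean_h: float) -> tuple[float, float, float]:
    """Return ``(a, d, d/a)`` from the three group means.

    ``a`` is half the parental range, ``d`` the hybrid's deviation from the
    midparent.  When the parents are equal (a = 0) the ratio is undefined
    and returned as NaN.
    """
    hp, lp = max(mean_cc, mean_ll), min(mean_cc, mean_ll)
    a = (hp - lp) / 2.0
    d = mean_h - (hp + lp) / 2.0
    da = d / a if a > 0 else float("nan")
    return a, d, da


def compute_parental_da(
    mean_maternal: float, mean_paternal: float, mean_h: float
) -> tuple[float, float]:
    """Return ``(a', d/a')`` where a' = (paternal - maternal)/2.

    d/a' = +1 when the hybrid tracks the paternal parent, -1 the maternal
    parent.  Undefined (NaN) when the parents are equal.
    """
    a_prime = (mean_paternal - mean_maternal) / 2.0
    d = mean_h - (mean_paternal + mean_maternal) / 2.0
    da_prime = d / a_prime if a_prime != 0 else float("nan")
    return a_prime, da_prime


# ---------------------------------------------------------------------------
# Pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternResult:
    pattern: str
    a: float
    d: float
    da: float
    p_mp: float
    p_hp: float
    p_lp: float


def midparent_test(
    cc: np.ndarray, ll: np.ndarray, h: np.ndarray, method: str = "propagated"
) -> float:
    """Two-sided p-value for hybrid mean == midparent.

    ``"propagated"`` treats the observed midparent as the estimate it is:
    Var[d] = s_H^2/n_H + (s_CC^2/n_CC + s_LL^2/n_LL)/4 with a
    Welch-Satterthwaite df.  ``"one_sample"`` is a one-sample t-test of the
    hybrid replicates against the observed midparent scalar.
    """
    mp = (cc.mean() + ll.mean()) / 2.0
    if method == "one_sample":
        if np.allclose(h, h[0]):  # zero variance: the t statistic degenerates
            return 1.0 if np.isclose(h[0], mp) else 0.0
        return float(stats.ttest_1samp(h, mp).pvalue)
    if method != "propagated":
        raise ValueError(f"unknown midparent test {method!r}")
    d = h.mean() - mp
    v_h = h.var(ddof=1) / len(h)
    v_cc = cc.var(ddof=1) / len(cc)
    v_ll = ll.var(ddof=1) / len(ll)
    v = v_h + (v_cc + v_ll) / 4.0
    if v == 0:
        return 1.0 if d == 0 else 0.0
    df = v**2 / (
        v_h**2 / (len(h) - 1)
        + (v_cc / 4.0) ** 2 / (len(cc) - 1)
        + (v_ll / 4.0) ** 2 / (len(ll) - 1)
    )
    t = d / np.sqrt(v)
    return float(2.0 * stats.t.sf(abs(t), df))


def _two_sample_p(x: np.ndarray, y: np.ndarray, equal_var: bool) -> float:
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        return 1.0 if np.isclose(x[0], y[0]) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def classify_pattern(
    values_cc,
    values_ll,
    values_h,
    alpha: float = DEFAULT_ALPHA,
    midparent: str = "propagated",
    equal_var: bool = False,
) -> PatternResult:
    """Assign one of the seven inheritance patterns to a DE cluster.

    Decision tree: a hybrid-vs-midparent test gates additive vs
    non-additive; the sign of d picks the high- or low-parent side; a
    hybrid-vs-parent t-test plus a mean comparison splits parent-like,
    beyond-parent and between-parent-and-midparent.  The d/a ratio is
    reported alongside but the categorical call rests on the tests.
    """
    cc = np.asarray(values_cc, dtype=float)
    ll = np.asarray(values_ll, dtype=float)
    h = np.asarray(values_h, dtype=float)
    for name, v in (("CC", cc), ("LL", ll), ("hybrid", h)):
        if v.size < 2:
            raise ValueError(f"group {name} needs at least 2 replicates")
    hp_vals, lp_vals = (cc, ll) if cc.mean() >= ll.mean() else (ll, cc)
    a, d, da = compute_da(cc.mean(), ll.mean(), h.mean())
    p_mp = midparent_test(cc, ll, h, method=midparent)
    p_hp = p_lp = float("nan")
    if p_mp > alpha:
        pattern = "additive"
    elif d > 0:
        p_hp = _two_sample_p(h, hp_vals, equal_var)
        if p_hp > alpha:
            pattern = "HP"
        elif h.mean() > hp_vals.mean():
            pattern = "AHP"
        else:
            pattern = "between_MP_HP"
    elif d < 0:
        p_lp = _two_sample_p(h, lp_vals, equal_var)
        if p_lp > alpha:
            pattern = "LP"
        elif h.mean() < lp_vals.mean():
            pattern = "BLP"
        else:
            pattern = "between_MP_LP"
    else:  # d == 0 cannot reject the midparent under either test
        raise AssertionError("d == 0 with a significant midparent test")
    return PatternResult(pattern=pattern, a=a, d=d, da=da, p_mp=p_mp, p_hp=p_hp, p_lp=p_lp)


# ---------------------------------------------------------------------------
# Per-cluster inheritance calls
# ---------------------------------------------------------------------------

def call_inheritance(
    matrix: ClusterCountMatrix,
    design: pd.DataFrame,
    set_id: str = "I",
    fdr: float = DEFAULT_FDR,
    alpha: float = DEFAULT_ALPHA,
    midparent: str = "propagated",
    equal_var: bool = False,
) -> pd.DataFrame:
    """ANOVA gate plus pattern classification for every cluster.

    Returns one row per cluster with the ANOVA p/q, the three group means,
    a, d, d/a (and a', d/a' for sets II/III), the tree's t-test p-values and
    the pattern label (empty for non-DE clusters).
    """
    groups = group_columns(design, set_id)
    de = anova_de(matrix, design, set_id=set_id, fdr=fdr)
    poo = ANALYSIS_SETS[set_id]["parent_of_origin"]
    rows = []
    for cluster_id, row in matrix.values.iterrows():
        cc = row[groups["CC"]].to_numpy(float)
        ll = row[groups["LL"]].to_numpy(float)
        h = row[groups["H"]].to_numpy(float)
        mean_cc, mean_ll, mean_h = cc.mean(), ll.mean(), h.mean()
        a, d, da = compute_da(mean_cc, mean_ll, mean_h)
        rec = {
            "cluster_id": cluster_id,
            "anova_p": de.loc[cluster_id, "p"],
            "anova_q": de.loc[cluster_id, "q"],
            "is_de": bool(de.loc[cluster_id, "is_de"]),
            "mean_CC": mean_cc,
            "mean_LL": mean_ll,
            "mean_H": mean_h,
            "a": a,
            "d": d,
            "da": da,
            "a_prime": float("nan"),
            "da_prime": float("nan"),
            "p_mp": float("nan"),
            "p_hp": float("nan"),
            "p_lp": float("nan"),
            "pattern": "",
        }
        if poo is not None:
            maternal, paternal = poo
            means = {"CC": mean_cc, "LL": mean_ll}
            rec["a_prime"], rec["da_prime"] = compute_parental_da(
                means[maternal], means[paternal], mean_h
            )
        if rec["is_de"]:
            res = classify_pattern(
                cc, ll, h, alpha=alpha, midparent=midparent, equal_var=equal_var
            )
            rec.update(
                {"p_mp": res.p_mp, "p_hp": res.p_hp, "p_lp": res.p_lp, "pattern": res.pattern}
            )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("cluster_id")


def summarize_patterns(calls: pd.DataFrame) -> pd.DataFrame:
    """Pattern counts and percentages over the DE clusters of one analysis set.

    Percentages are 100 * count / n_DE rounded to one decimal.  The additive
    row is the MP pattern; non-additive aggregates the other six.
    """
    de = calls[calls["is_de"] & (calls["pattern"] != "")]
    n_de = len(de)
    rows = [("DE clusters", n_de)]
    counts = de["pattern"].value_counts()
    rows.append(("additive", int(counts.get("additive", 0))))
    rows.append(("non_additive", int(sum(counts.get(p, 0) for p in NON_ADDITIVE))))
    for p in NON_ADDITIVE:
        rows.append((p, int(counts.get(p, 0))))
    out = pd.DataFrame(rows, columns=["pattern", "count"]).set_index("pattern")
    if n_de > 0:
        pct = (100.0 * out["count"] / n_de).round(1)
        pct.loc["DE clusters"] = float("nan")
        out["percent"] = pct
    else:
        out = out.iloc[0:0]
        out["percent"] = pd.Series(dtype=float)
    return out
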