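"""Segmentation evaluation: the Dice similarity coefficient and the
statistical comparison suite over per-patient DSC tables.

The DSC between reference mask A and prediction B is

    DSC = (2 |A ∩ B| + eps) / (|A| + |B| + eps),   eps = 1e-7,

where the smoothing term keeps the ratio defined (and equal to 1) when both
masks are empty.  DSC tables are tidy DataFrames with columns
(patient, organ, model, cohort, age, dsc).

The comparison machinery mirrors a multi-model evaluation protocol:

* Kruskal–Wallis H across models per organ, Holm-corrected across organs,
  with Dunn's rank-based post-hoc pairwise tests for organs that survive;
* Mann–Kendall trend of DSC with patient age per model × organ (original
  test: tie-corrected variance, continuity-corrected normal z, tau-b),
  Benjamini–Hochberg FDR across the batch;
* on a detected trend, a two-sided Mann–Whitney U between the < 10 and
  ≥ 10 year age groups (age exactly 10 falls in the older group);
* validation-vs-test cohort Mann–Whitney U per model × organ with FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EPSILON = 1e-7

RECORD_COLUMNS = ["patient", "organ", "model", "cohort", "age", "dsc"]


@dataclass
class StatsConfig:
    alpha_holm: float = 0.05
    alpha_fdr: float = 0.05
    alpha_pairwise: float = 0.05
    age_split: float = 10.0
    epsilon: float = EPSILON
    dunn_adjust: bool = False  # within-family Holm adjustment of Dunn p-values

    def __post_init__(self) -> None:
        for a in (self.alpha_holm, self.alpha_fdr, self.alpha_pairwise):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")


class TestKind(str, Enum):
    kruskal_wallis = "kruskal_wallis"
    dunn = "dunn"
    mann_kendall = "mann_kendall"
    mann_whitney = "mann_whitney"


@dataclass
class StatResult:
    test: TestKind
    organ: str
    grouping: str  # e.g. "models", "modelA|modelB", "age<10 vs age>=10"
    statistic: float
    p_raw: float
    p_adjusted: float
    adjust_method: str  # holm_bonferroni | fdr_bh | none
    significant: bool
    model: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# the metric
# ---------------------------------------------------------------------------

def dsc(A: np.ndarray, B: np.ndarray, epsilon: float = EPSILON) -> float:
    """3D Dice similarity coefficient with a smoothing term."""
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    A = A.astype(bool)
    B = B.astype(bool)
    inter = np.count_nonzero(A & B)
    return float((2.0 * inter + epsilon)
                 / (np.count_nonzero(A) + np.count_nonzero(B) + epsilon))


def records_from_masks(
    entries: list[tuple[str, str, str, str, float, np.ndarray, np.ndarray]],
    epsilon: float = EPSILON,
) -> pd.DataFrame:
    """Build a DSC table from (patient, organ, model, cohort, age, ref, pred)."""
    rows = []
    for patient, organ, model, cohort, age, ref, pred in entries:
        rows.append((patient, organ, model, cohort, age, dsc(ref, pred, epsilon)))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# Mann–Kendall trend test (original variant)
# ---------------------------------------------------------------------------

def mann_kendall(x: np.ndarray) -> tuple[float, float, float, float]:
    """Original Mann–Kendall test on an ordered sequence.

    Returns ``(tau, p, S, z)``: the tie-corrected tau-b statistic, the
    two-sided p-value from the continuity-corrected normal approximation,
    the raw S score and the z statistic.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Mann–Kendall requires at least 4 observations")
    diff = np.sign(x[None, :] - x[:, None])
    S = float(np.triu(diff, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    n_pairs = n * (n - 1) / 2.0
    tie_term = np.sum(ties * (ties - 1)) / 2.0
    denom = np.sqrt((n_pairs - tie_term) * n_pairs)
    tau = S / denom if denom > 0 else 0.0

    if var_s <= 0:
        return tau, 1.0, S, 0.0
    if S > 0:
        z = (S - 1) / np.sqrt(var_s)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(tau), float(min(p, 1.0)), S, float(z)


# ---------------------------------------------------------------------------
# Dunn's post-hoc test
# ---------------------------------------------------------------------------

def dunn_pairwise(groups: dict[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's rank-based multiple-comparison z tests with tie correction.

    Returns one (name_a, name_b, z, p_raw) per unordered pair.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    sizes = [len(groups[k]) for k in names]
    N = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for name, n_i in zip(names, sizes):
        mean_ranks[name] = ranks[start:start + n_i].mean()
        start += n_i
    _, counts = np.unique(values, return_counts=True)
    ties = counts[counts > 1]
    tie_corr = np.sum(ties**3 - ties) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_corr
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            out.append((a, b, float(z), float(min(p, 1.0))))
    return out


# ---------------------------------------------------------------------------
# the comparison protocol
# ---------------------------------------------------------------------------

def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"DSC table lacks columns {missing}")
    return records


def compare_models(records: pd.DataFrame, cfg: StatsConfig | None = None,
                   organs: list[str] | None = None) -> list[StatResult]:
    """Kruskal–Wallis per organ (Holm across organs) + Dunn post hoc.

    Dunn pairwise results are produced only for organs whose Holm-adjusted
    Kruskal–Wallis p-value is significant; they are reported unadjusted
    within the organ's family unless ``cfg.dunn_adjust`` is set.
    """
    cfg = cfg or StatsConfig()
    records = _check_records(records)
    organs = organs or sorted(records["organ"].unique())
    kw: list[tuple[str, float, float, dict]] = []
    for organ in organs:
        sub = records[records["organ"] == organ]
        groups = {m: g["dsc"].to_numpy() for m, g in sub.groupby("model")}
        if len(groups) < 2:
            raise ValueError(f"organ {organ}: need >= 2 models to compare")
        if any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"organ {organ}: need >= 2 records per model")
        vals = list(groups.values())
        if all(np.array_equal(v, vals[0]) for v in vals[1:]):
            H, p = 0.0, 1.0  # identical groups: no evidence of difference
        else:
            H, p = stats.kruskal(*vals)
        kw.append((organ, float(H), float(p), groups))

    reject, p_adj, _, _ = multipletests([r[2] for r in kw], alpha=cfg.alpha_holm,
                                        method="holm")
    results: list[StatResult] = []
    for (organ, H, p, groups), pa, rej in zip(kw, p_adj, reject):
        results.append(StatResult(
            TestKind.kruskal_wallis, organ, "models", H, p, float(pa),
            "holm_bonferroni", bool(rej)))
        if not rej:
            continue
        pairs = dunn_pairwise(groups)
        praws = [p_ab for (_, _, _, p_ab) in pairs]
        if cfg.dunn_adjust and pairs:
            rej_d, p_adj_d, _, _ = multipletests(praws, alpha=cfg.alpha_pairwise,
                                                 method="holm")
            adj_method = "holm_bonferroni"
        else:
            p_adj_d = praws
            rej_d = [pp <= cfg.alpha_pairwise for pp in praws]
            adj_method = "none"
        for (a, b, z, p_ab), pa_d, rj in zip(pairs, p_adj_d, rej_d):
            results.append(StatResult(
                TestKind.dunn, organ, f"{a}|{b}", z, p_ab, float(pa_d),
                adj_method, bool(rj)))
    return results


def trend_with_age(records: pd.DataFrame, cfg: StatsConfig | None = None
                   ) -> list[StatResult]:
    """Mann–Kendall DSC-vs-age trend per model × organ, FDR across the batch."""
    cfg = cfg or StatsConfig()
    records = _check_records(records)
    rows = []
    for (model, organ), sub in records.groupby(["model", "organ"], sort=True):
        sub = sub.sort_values("age", kind="stable")
        if len(sub) < 4:
            raise ValueError(f"{model}/{organ}: need >= 4 records for a trend test")
        tau, p, S, z = mann_kendall(sub["dsc"].to_numpy())
        rows.append((model, organ, tau, p, S, z))
    reject, p_adj, _, _ = multipletests([r[3] for r in rows], alpha=cfg.alpha_fdr,
                                        method="fdr_bh")
    return [
        StatResult(TestKind.mann_kendall, organ, "age", tau, p, float(pa),
                   "fdr_bh", bool(rej), model=model, extra={"S": S, "z": z})
        for (model, organ, tau, p, S, z), pa, rej in zip(rows, p_adj, reject)
    ]


def age_group_compare(records: pd.DataFrame, model: str, organ: str,
                      cfg: StatsConfig | None = None) -> StatResult:
    """Two-sided Mann–Whitney U between the < 10 and ≥ 10 year groups."""
    cfg = cfg or StatsConfig()
    records = _check_records(records)
    sub = records[(records["model"] == model) & (records["organ"] == organ)]
    young = sub[sub["age"] < cfg.age_split]["dsc"].to_numpy()
    old = sub[sub["age"] >= cfg.age_split]["dsc"].to_numpy()
    if len(young) == 0 or len(old) == 0:
        raise ValueError("both age groups must be nonempty")
    U, p = stats.mannwhitneyu(young, old, alternative="two-sided", method="auto")
    return StatResult(
        TestKind.mann_whitney, organ,
        f"age<{cfg.age_split:g} vs age>={cfg.age_split:g}",
        float(U), float(p), float(p), "none", bool(p <= cfg.alpha_pairwise),
        model=model,
        extra={"n_young": len(young), "n_old": len(old)})


def dataset_compare(records: pd.DataFrame, cfg: StatsConfig | None = None,
                    cohorts: tuple[str, str] = ("validation", "test")
                    ) -> list[StatResult]:
    """Validation-vs-test Mann–Whitney U per model × organ, FDR controlled."""
    cfg = cfg or StatsConfig()
    records = _check_records(records)
    rows = []
    for (model, organ), sub in records.groupby(["model", "organ"], sort=True):
        a = sub[sub["cohort"] == cohorts[0]]["dsc"].to_numpy()
        b = sub[sub["cohort"] == cohorts[1]]["dsc"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"{model}/{organ}: both cohorts must be present")
        U, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append((model, organ, float(U), float(p)))
    reject, p_adj, _, _ = multipletests([r[3] for r in rows], alpha=cfg.alpha_fdr,
                                        method="fdr_bh")
    return [
        StatResult(TestKind.mann_whitney, organ, f"{cohorts[0]}|{cohorts[1]}",
                   U, p, float(pa), "fdr_bh", bool(rej), model=model)
        for (model, organ, U, p), pa, rej in zip(rows, p_adj, reject)
    ]


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def summarize(records: pd.DataFrame, cfg: StatsConfig | None = None
              ) -> dict[str, pd.DataFrame]:
    """Mean ± SD per organ × model × cohort plus all test results.

    Returns {"dsc_summary": ..., "stats": ...} ready for delimited export.
    The SD is the population standard deviation (a single record has SD 0).
    """
    cfg = cfg or StatsConfig()
    records = _check_records(records)
    if records.empty:
        raise ValueError("empty DSC table")
    summary = (records.groupby(["organ", "model", "cohort"], observed=True)["dsc"]
               .agg(mean="mean", std=lambda s: float(np.std(s, ddof=0)), n="count")
               .reset_index())

    results: list[StatResult] = []
    n_models = records["model"].nunique()
    if n_models >= 2 and (records.groupby(["organ", "model"]).size() >= 2).all():
        results += compare_models(records, cfg)
    if (records.groupby(["model", "organ"]).size() >= 4).all():
        trends = trend_with_age(records, cfg)
        results += trends
        for t in trends:
            if not t.significant:
                continue
            sub = records[(records["model"] == t.model)
                          & (records["organ"] == t.organ)]
            if ((sub["age"] < cfg.age_split).any()
                    and (sub["age"] >= cfg.age_split).any()):
                results.append(age_group_compare(records, t.model, t.organ, cfg))
    cohorts = records["cohort"].unique()
    if {"validation", "test"} <= set(cohorts):
        both = records[records["cohort"].isin(["validation", "test"])]
        sizes = both.groupby(["model", "organ", "cohort"]).size()
        if (sizes > 0).all() and sizes.groupby(["model", "organ"]).count().eq(2).all():
            results += dataset_compare(both, cfg)

    stats_df = pd.DataFrame([{
        "test": r.test.value, "organ": r.organ, "model": r.model,
        "grouping": r.grouping, "statistic": r.statistic, "p_raw": r.p_raw,
        "p_adjusted": r.p_adjusted, "adjust_method": r.adjust_method,
        "significant": r.significant,
    } for r in results])
    return {"dsc_summary": summary, "stats": stats_df}


def write_report(tables: dict[str, pd.DataFrame], directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(directory / f"{name}.tsv", sep="\t", index=False)
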