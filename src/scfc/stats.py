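"""Statistical battery for the structure-function coupling analysis.

The atom of every comparison is a correlation record: one Pearson r between
observed and predicted FC per (subject, model, band, weight).  On top of
those this module provides

* paired t-tests between edge-weight conditions,
* the SC-shuffling individuality test (does a subject's own SC predict
  their FC better than someone else's?),
* age trends of prediction accuracy,
* healthy-vs-patient comparisons: Mann-Whitney U (exact for the small
  patient group) with Cohen's d, matrix-similarity distributions, total
  connection strength,
* Spearman correlations between prediction error (1 - r) and PANSS symptom
  scores, exact for small n,
* an exact label-permutation test for model-vs-model comparisons,
* Benjamini-Hochberg FDR control, and
* per-edge across-subject variability of the FC bands.

Exact small-sample procedures matter here because the patient group has
five members: the attainable two-sided Mann-Whitney p for complete 5-vs-5
separation is 2/252, and one-sided label-permutation p-values move on a
grid of 1/252.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ConnectivityMatrix, ConnectomeError, upper_triangle


class DegenerateDataError(ConnectomeError):
    """Input data degenerate for the requested test (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


def pearson_edges(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Pearson correlation between the upper-triangle edges of two matrices."""
    if a.parcellation.labels != b.parcellation.labels:
        raise ConnectomeError("matrices are over different parcellations")
    x, y = a.edges(), b.edges()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant edge vector: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def cohens_d(a, b) -> float:
    """Standardized mean difference (a - b) with pooled Bessel-corrected SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("Cohen's d needs at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise DegenerateDataError("zero pooled SD")
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    cohens_d: float
    n_a: int
    n_b: int
    method: str


def mannwhitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U with Cohen's d.

    Exact null distribution when the smaller group has <= 8 members and
    there are no ties (the 5-patient comparisons demand it); tie-corrected
    normal approximation otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("empty group")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if min(a.size, b.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
        if has_ties and min(a.size, b.size) <= 8:
            warnings.warn(
                "ties with a small group: falling back to the tie-corrected "
                "normal approximation",
                stacklevel=2,
            )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    d = cohens_d(a, b) if min(a.size, b.size) >= 2 else np.nan
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=d,
        n_a=a.size,
        n_b=b.size,
        method=method,
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def _clip_p(p) -> np.ndarray:
    """Computed p-values of exactly 0 become the smallest positive float."""
    return np.maximum(np.asarray(p, dtype=float), np.nextafter(0.0, 1.0))


@dataclass
class FdrResult:
    p_values: np.ndarray
    labels: list
    alpha: float
    significant: np.ndarray
    threshold: float | None  # largest p declared significant, None if no flags


def bh_fdr(p_values, labels=None, alpha: float = 0.05,
           variant: str = "bh") -> FdrResult:
    """Benjamini-Hochberg step-up FDR control.

    Finds the largest k with p_(k) <= k * alpha / m (with the extra
    harmonic-sum factor for the ``by`` variant) and flags all p <= p_(k).
    Bounded p-values reported as e.g. "<1e-10" should be entered as their
    upper bound.  Flags are monotone in p, and m = 1 reduces to raw alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ConnectomeError("p-values must lie in (0, 1]")
    m = p.size
    denom = np.sum(1.0 / np.arange(1, m + 1)) if variant == "by" else 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) * alpha) / (m * denom)
    passing = np.flatnonzero(ranked <= crit)
    if passing.size:
        threshold = float(ranked[passing[-1]])
        significant = p <= threshold
    else:
        threshold = None
        significant = np.zeros(m, dtype=bool)
    return FdrResult(
        p_values=p,
        labels=list(labels) if labels is not None else list(range(m)),
        alpha=alpha,
        significant=significant,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# records-level analyses
# ---------------------------------------------------------------------------


def paired_ttest_weights(records: pd.DataFrame, band: str,
                         weight_a: str, weight_b: str) -> float:
    """Two-sided paired t-test on per-subject r between two SC weightings."""
    sub = records[records.band == band]
    a = sub[sub.weight == weight_a].set_index("subject").r
    b = sub[sub.weight == weight_b].set_index("subject").r
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise DegenerateDataError("need >= 3 paired subjects")
    diffs = (a.loc[common] - b.loc[common]).to_numpy()
    if np.ptp(diffs) == 0:
        raise DegenerateDataError(
            "zero-variance paired differences: t-test undefined"
        )
    return float(sps.ttest_rel(a.loc[common], b.loc[common]).pvalue)


def all_weight_pairs_ttests(records: pd.DataFrame, alpha: float = 0.05):
    """Paired t-tests for every (band, weight pair); BH-FDR across all."""
    bands = sorted(records.band.unique())
    weights = sorted(records.weight.unique())
    rows = []
    for band in bands:
        for wa, wb in combinations(weights, 2):
            rows.append(
                {
                    "band": band,
                    "weight_a": wa,
                    "weight_b": wb,
                    "p": paired_ttest_weights(records, band, wa, wb),
                }
            )
    df = pd.DataFrame(rows)
    fdr = bh_fdr(_clip_p(df.p.to_numpy()), alpha=alpha)
    df["significant"] = fdr.significant
    return df, fdr.threshold


def age_correlation(records: pd.DataFrame, ages: dict,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of accuracy r with age per (band, weight).

    BH-FDR is applied across all conditions present in the records.
    """
    age_arr = pd.Series(ages)
    if age_arr.nunique() < 2:
        raise DegenerateDataError("ages are constant")
    rows = []
    for (band, weight), grp in records.groupby(["band", "weight"]):
        if len(grp) < 3:
            raise DegenerateDataError("need >= 3 subjects per condition")
        r_vals = grp.set_index("subject").r
        common = r_vals.index.intersection(age_arr.index)
        res = sps.pearsonr(age_arr.loc[common], r_vals.loc[common])
        rows.append(
            {"band": band, "weight": weight,
             "r": float(res.statistic), "p": float(res.pvalue)}
        )
    df = pd.DataFrame(rows)
    fdr = bh_fdr(_clip_p(df.p.to_numpy()), alpha=alpha)
    df["significant"] = fdr.significant
    return df


# ---------------------------------------------------------------------------
# individuality shuffling
# ---------------------------------------------------------------------------


def shuffle_individuality(subject_ids, score_fn, n_perm: int = 500,
                          seed: int = 0) -> pd.DataFrame:
    """SC-shuffling individuality test.

    ``score_fn(donor_id, target_id)`` must return the accuracy r obtained
    when the donor subject's structural matrices predict the target
    subject's observed FC.  Each of the ``n_perm`` rounds applies one
    uniform permutation of the SC assignment across subjects (fixed points
    allowed); per target subject the r values are averaged over rounds.

    Returns a DataFrame with columns subject, r_unshuffled, r_shuffled_mean.
    """
    if n_perm < 1:
        raise ConnectomeError("n_perm must be >= 1")
    ids = list(subject_ids)
    rng = np.random.default_rng(seed)
    unshuffled = {sid: score_fn(sid, sid) for sid in ids}
    sums = {sid: 0.0 for sid in ids}
    for _ in range(n_perm):
        perm = rng.permutation(len(ids))
        for k, sid in enumerate(ids):
            sums[sid] += score_fn(ids[perm[k]], sid)
    return pd.DataFrame(
        {
            "subject": ids,
            "r_unshuffled": [unshuffled[sid] for sid in ids],
            "r_shuffled_mean": [sums[sid] / n_perm for sid in ids],
        }
    )


def analytical_shuffle_scorer(cohort, weight: str, band: str, **model_kwargs):
    """Efficient ``score_fn`` for the analytical model.

    Communication predictors are computed once per subject; each shuffled
    evaluation is then a single OLS refit.
    """
    from .analytical import AnalyticalFCModel, build_predictors

    designs, targets = {}, {}
    for s in cohort.subjects:
        pred = build_predictors(
            cohort.get(s.id, "SC", weight), cohort.get(s.id, "ED", None),
            si_memory=model_kwargs.get("si_memory", False),
            length_transform=model_kwargs.get("length_transform", "inv"),
        )
        designs[s.id] = pred.design()
        targets[s.id] = cohort.get(s.id, "FC", band).edges()

    def score(donor_id: str, target_id: str) -> float:
        model = AnalyticalFCModel().fit(designs[donor_id], targets[target_id])
        return model.r_

    return score


# ---------------------------------------------------------------------------
# patient comparisons
# ---------------------------------------------------------------------------


def group_comparison_records(records: pd.DataFrame, groups: dict,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Healthy-vs-psychosis Mann-Whitney U on r per (band, weight) + FDR."""
    rows = []
    for (band, weight), grp in records.groupby(["band", "weight"]):
        g = grp.assign(group=grp.subject.map(groups))
        healthy = g[g.group == "healthy"].r.to_numpy()
        patient = g[g.group == "psychosis"].r.to_numpy()
        comp = mannwhitney(healthy, patient)
        rows.append(
            {
                "band": band,
                "weight": weight,
                "U": comp.u_statistic,
                "p": comp.p_value,
                "cohens_d": comp.cohens_d,
                "n_healthy": comp.n_a,
                "n_psychosis": comp.n_b,
            }
        )
    df = pd.DataFrame(rows)
    fdr = bh_fdr(_clip_p(df.p.to_numpy()), alpha=alpha)
    df["significant"] = fdr.significant
    return df


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho with exact two-sided permutation p for n <= 9.

    Ties are handled by mid-ranks.  For larger n the t-approximation from
    scipy is used.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    if n < 3:
        raise DegenerateDataError("need >= 3 observations")
    rho = float(sps.spearmanr(x, y).statistic)
    if n > 9:
        return rho, float(sps.spearmanr(x, y).pvalue)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        rho_p = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += rho_p >= obs - 1e-12
        total += 1
    return rho, count / total


def spearman_panss(records: pd.DataFrame, panss: dict,
                   score: str = "total") -> pd.DataFrame:
    """Spearman rho between prediction error (1 - r) and PANSS per condition.

    ``panss`` maps subject id -> PanssScores; only subjects present in both
    the records and the PANSS table enter.
    """
    rows = []
    for (band, weight), grp in records.groupby(["band", "weight"]):
        sub = grp[grp.subject.isin(panss)]
        if len(sub) < 3:
            raise DegenerateDataError("need >= 3 patients with PANSS scores")
        err = 1.0 - sub.r.to_numpy()
        scores = np.array([getattr(panss[s], score) for s in sub.subject])
        rho, p = spearman_exact(scores, err)
        rows.append({"band": band, "weight": weight, "rho": rho, "p": p})
    return pd.DataFrame(rows)


@dataclass
class PermutationTestResult:
    observed: float
    n_permutations: int
    p_value: float
    sided: str
    exact: bool


def exact_label_permutation(a, b, sided: str = "two",
                            max_exact: int = 184756,
                            n_monte_carlo: int = 10000,
                            seed: int = 0) -> PermutationTestResult:
    """Label-permutation test on the difference of group means.

    All C(|a|+|b|, |a|) relabelings are enumerated when feasible (p is then
    a multiple of 1/C and never smaller than 1/C); otherwise a seeded
    Monte-Carlo sample of relabelings is used.  ``sided``: 'two' compares
    |difference|, 'one' tests mean(a) > mean(b).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("empty group")
    pooled = np.concatenate([a, b])
    n_a, n_total = a.size, a.size + b.size
    observed = a.mean() - b.mean()
    n_exact = comb(n_total, n_a)
    eps = 1e-12

    def stat(idx_a):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(idx_a)] = True
        return pooled[mask].mean() - pooled[~mask].mean()

    if n_exact <= max_exact:
        stats_all = np.fromiter(
            (stat(c) for c in combinations(range(n_total), n_a)),
            dtype=float,
            count=n_exact,
        )
        if sided == "two":
            count = int(np.sum(np.abs(stats_all) >= abs(observed) - eps))
        else:
            count = int(np.sum(stats_all >= observed - eps))
        return PermutationTestResult(
            observed=float(observed),
            n_permutations=n_exact,
            p_value=count / n_exact,
            sided=sided,
            exact=True,
        )
    rng = np.random.default_rng(seed)
    count = 1  # include the observed labeling
    for _ in range(n_monte_carlo):
        idx = rng.choice(n_total, size=n_a, replace=False)
        s = stat(idx)
        if sided == "two":
            count += abs(s) >= abs(observed) - eps
        else:
            count += s >= observed - eps
    return PermutationTestResult(
        observed=float(observed),
        n_permutations=n_monte_carlo,
        p_value=count / (n_monte_carlo + 1),
        sided=sided,
        exact=False,
    )


def model_comparison(records_a: pd.DataFrame, records_b: pd.DataFrame,
                     sided: str = "one", alpha: float = 0.05) -> pd.DataFrame:
    """Permutation test between two models' r distributions per condition."""
    rows = []
    keys = sorted(
        set(map(tuple, records_a[["band", "weight"]].drop_duplicates().values))
        & set(map(tuple, records_b[["band", "weight"]].drop_duplicates().values))
    )
    for band, weight in keys:
        ra = records_a[(records_a.band == band) & (records_a.weight == weight)].r
        rb = records_b[(records_b.band == band) & (records_b.weight == weight)].r
        res = exact_label_permutation(ra.to_numpy(), rb.to_numpy(), sided=sided)
        rows.append(
            {"band": band, "weight": weight, "observed_diff": res.observed,
             "p": res.p_value, "exact": res.exact}
        )
    df = pd.DataFrame(rows)
    fdr = bh_fdr(_clip_p(df.p.to_numpy()), alpha=alpha)
    df["significant"] = fdr.significant
    return df


# ---------------------------------------------------------------------------
# matrix-level summaries
# ---------------------------------------------------------------------------


def matrix_cohort_similarity(target: ConnectivityMatrix,
                             cohort_matrices: dict) -> pd.DataFrame:
    """Pearson r of a target matrix against each cohort member's matrix.

    Also returns, on every row, the mean of the pairwise correlations among
    the cohort matrices themselves (the healthy-vs-healthy reference line).
    """
    edges = {sid: upper_triangle(m.values) for sid, m in cohort_matrices.items()}
    t_edges = target.edges()
    if np.ptp(t_edges) == 0:
        raise DegenerateDataError("constant target matrix")
    ids = sorted(edges)
    stack = np.array([edges[sid] for sid in ids])
    cc = np.corrcoef(stack)
    iu = np.triu_indices(len(ids), k=1)
    reference = float(cc[iu].mean())
    rows = [
        {"cohort_subject": sid,
         "r": float(np.corrcoef(t_edges, edges[sid])[0, 1]),
         "healthy_reference": reference}
        for sid in ids
    ]
    return pd.DataFrame(rows)


def total_strength(m: ConnectivityMatrix) -> float:
    """Sum of the upper-triangle edge weights."""
    return float(m.edges().sum())


def strength_group_comparison(cohort, alpha: float = 0.05,
                              healthy_ids=None) -> pd.DataFrame:
    """Mann-Whitney on total strength per condition (5 SC weights + 4 bands).

    ``healthy_ids`` restricts the healthy group (e.g. to the age-matched
    subset); BH-FDR is applied across the 9 conditions.
    """
    from .core import FC_BANDS, SC_VARIANTS

    healthy = healthy_ids or [s.id for s in cohort.healthy]
    patients = [s.id for s in cohort.patients]
    rows = []
    conditions = [("SC", v) for v in SC_VARIANTS] + [("FC", b) for b in FC_BANDS]
    for kind, variant in conditions:
        h_vals = [total_strength(cohort.get(sid, kind, variant)) for sid in healthy]
        p_vals = [total_strength(cohort.get(sid, kind, variant)) for sid in patients]
        comp = mannwhitney(h_vals, p_vals)
        rows.append(
            {"kind": kind, "variant": variant, "U": comp.u_statistic,
             "p": comp.p_value, "cohens_d": comp.cohens_d}
        )
    df = pd.DataFrame(rows)
    fdr = bh_fdr(_clip_p(df.p.to_numpy()), alpha=alpha)
    df["significant"] = fdr.significant
    return df


def edge_variability(cohort, band: str, subject_ids=None) -> np.ndarray:
    """Across-subject sample SD of each FC edge (matrices max-normalized).

    Returns the distribution over edges; its median summarizes how variable
    the band's connectivity is across the cohort.
    """
    from .core import normalize_matrix

    ids = subject_ids or [s.id for s in cohort.subjects]
    if len(ids) < 3:
        raise DegenerateDataError("need >= 3 subjects")
    stack = np.array(
        [normalize_matrix(cohort.get(sid, "FC", band)).edges() for sid in ids]
    )
    return stack.std(axis=0, ddof=1)


def band_variability_comparison(cohort, subject_ids=None) -> pd.DataFrame:
    """Median edge-SD per band plus band-vs-band two-sided t-tests."""
    from .core import FC_BANDS

    sds = {band: edge_variability(cohort, band, subject_ids) for band in FC_BANDS}
    rows = []
    for band in FC_BANDS:
        rows.append({"band": band, "median_sd": float(np.median(sds[band]))})
    medians = pd.DataFrame(rows)
    tests = []
    for ba, bb in combinations(FC_BANDS, 2):
        res = sps.ttest_ind(sds[ba], sds[bb])
        tests.append({"band_a": ba, "band_b": bb, "p": float(res.pvalue)})
    return medians, pd.DataFrame(tests)
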