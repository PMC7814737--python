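"""Downstream analytics on observed or predicted promoter activity.

Covers: calling promoters active/inactive with a two-component Gaussian
mixture per sample; pairwise sample-specific activity fractions;
differential activity between groups (Wilcoxon rank-sum with
Benjamini-Hochberg FDR); alternative primary-promoter usage between
groups; regression evaluation (squared Pearson R2, RMSE, optional
mappability filter); gene-level consistency between activity and RNA
expression; and a per-feature predictive-utility screen.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# activity calling
# ----------------------------------------------------------------------
class ActivityCaller(BaseEstimator):
    """Two-component Gaussian mixture classifier for promoter activity.

    Promoter enrichment is bimodal: an inactive mode near/below zero and
    an active mode at high enrichment.  A univariate 2-component GMM is
    fit per sample (EM, k-means initialization, fixed seed); the
    component with the larger mean is labeled ``active`` and promoters
    are assigned by maximum posterior.
    """

    def __init__(self, random_state=0, max_iter=200, tol=1e-6, max_retries=3):
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.max_retries = max_retries

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct enrichment values")
        last_err = None
        for attempt in range(self.max_retries):
            gmm = GaussianMixture(
                n_components=2,
                covariance_type="full",
                max_iter=self.max_iter,
                tol=self.tol,
                init_params="kmeans",
                random_state=None if self.random_state is None else self.random_state + attempt,
                reg_covar=1e-6,
            )
            gmm.fit(x)
            if gmm.converged_:
                self.gmm_ = gmm
                break
            last_err = RuntimeError("EM did not converge")
        else:
            raise last_err
        self.active_component_ = int(np.argmax(self.gmm_.means_.ravel()))
        return self

    def predict(self, X):
        """Return (states, posteriors): states in {"active", "inactive"}."""
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        resp = self.gmm_.predict_proba(x)
        assigned = resp.argmax(axis=1)
        posterior = resp[np.arange(len(x)), assigned]
        states = np.where(assigned == self.active_component_, "active", "inactive")
        return states, posterior


def call_activity(enrichment, transcript_ids=None, random_state=0) -> pd.DataFrame:
    """Per-promoter activity calls for one sample.

    Accepts an ``EnrichmentVector`` or a plain array (with explicit
    ``transcript_ids``).  Returns transcript_id, state, posterior.
    """
    values = getattr(enrichment, "values", enrichment)
    if transcript_ids is None:
        transcript_ids = getattr(enrichment, "transcript_ids", np.arange(len(values)))
    caller = ActivityCaller(random_state=random_state).fit(values)
    states, posterior = caller.predict(values)
    if (states == states[0]).all():
        logger.warning("all promoters called %s; enrichment may be unimodal", states[0])
    return pd.DataFrame(
        {"transcript_id": np.asarray(transcript_ids), "state": states, "posterior": posterior}
    )


def sample_specific_fraction(calls_by_sample: dict) -> pd.DataFrame:
    """Pairwise fraction of active promoters private to one sample.

    For samples A, B with active sets a, b the fraction is
    ``|a XOR b| / |a U b]``; an empty union yields NaN.
    """
    active = {
        s: set(df.loc[df["state"] == "active", "transcript_id"])
        for s, df in calls_by_sample.items()
    }
    rows = []
    for a, b in itertools.combinations(sorted(active), 2):
        union = active[a] | active[b]
        if not union:
            frac = np.nan
        else:
            frac = len(active[a] ^ active[b]) / len(union)
        rows.append((a, b, frac))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "fraction"])


# ----------------------------------------------------------------------
# rank-sum machinery
# ----------------------------------------------------------------------
@lru_cache(maxsize=64)
def _comb_indices(n_a: int, n_total: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n_total), n_a)), dtype=np.intp)

#: largest per-group size for which the exact enumeration is used
EXACT_MAX_N = 20


def ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic, p).

    The statistic is the rank sum of group ``a``.  For group sizes up to
    ``EXACT_MAX_N`` the p-value is the exact proportion of group-label
    assignments whose rank sum deviates from its null mean at least as
    much as the observed one (tie patterns handled by mid-ranks); larger
    groups use the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n_a].sum())
    mu = n_a * (n_a + n_b + 1) / 2.0
    if max(n_a, n_b) <= EXACT_MAX_N:
        combs = _comb_indices(n_a, n_a + n_b)
        null = ranks[combs].sum(axis=1)
        p = float(np.mean(np.abs(null - mu) >= abs(w - mu) - 1e-9))
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return w, min(p, 1.0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def differential_activity(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    transcript_ids=None,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """Per-promoter two-group comparison of activity values.

    ``group_a``/``group_b`` are (promoters x samples) matrices aligned on
    rows.  Each promoter gets a two-sided Wilcoxon rank-sum p-value and
    a BH-adjusted q-value; ``significant`` flags q < ``fdr_level``.
    """
    A = np.asarray(getattr(group_a, "values", group_a), dtype=float)
    B = np.asarray(getattr(group_b, "values", group_b), dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("groups are not aligned on promoters")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if transcript_ids is None:
        transcript_ids = getattr(group_a, "index", pd.RangeIndex(A.shape[0]))
    stats_w = np.empty(A.shape[0])
    pvals = np.empty(A.shape[0])
    for i in range(A.shape[0]):
        stats_w[i], pvals[i] = ranksum_pvalue(A[i], B[i])
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "transcript_id": np.asarray(transcript_ids),
            "mean_a": A.mean(axis=1),
            "mean_b": B.mean(axis=1),
            "statistic": stats_w,
            "p": pvals,
            "q": qvals,
            "significant": qvals < fdr_level,
        }
    )


# ----------------------------------------------------------------------
# promoter usage
# ----------------------------------------------------------------------
def promoter_usage(
    activity: pd.DataFrame,
    groups: dict,
    gene_map: dict,
    active_threshold: float = 1.0,
    usage_delta: float = 0.4,
    activity_delta: float | None = 1.0,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """Alternative primary-promoter usage between two sample groups.

    Parameters
    ----------
    activity
        DataFrame (promoters x samples) of activity values, indexed by
        transcript_id.
    groups
        Mapping sample -> group label; exactly two groups, ordered by
        sorted label (group 1 minus group 2 fixes the score sign).
    gene_map
        Mapping transcript_id -> gene_id.

    A gene is *active* in a group when its most active promoter's
    group-mean exceeds ``active_threshold``.  The *primary* promoter per
    group is the argmax of group-mean activity (ties to the smaller
    transcript_id).  Candidate genes are active in both groups with
    different primary promoters and, when ``activity_delta`` is set, a
    between-group change of at least that much for one of the two
    primary promoters.  The per-sample usage score is
    ``activity(primary of group 1) - activity(primary of group 2)``;
    groups are compared by rank-sum with BH adjustment, and
    ``usage_delta`` screens on the absolute between-group difference of
    mean usage scores.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    g1_samples = [s for s in activity.columns if groups.get(s) == labels[0]]
    g2_samples = [s for s in activity.columns if groups.get(s) == labels[1]]
    genes = pd.Series({t: gene_map.get(t) for t in activity.index}, name="gene_id")
    missing = genes.isna()
    if missing.any():
        logger.info("%d promoters absent from the gene map; skipped", int(missing.sum()))
    mean1 = activity[g1_samples].mean(axis=1)
    mean2 = activity[g2_samples].mean(axis=1)

    rows = []
    for gene, tids in genes.dropna().groupby(genes.dropna()).groups.items():
        tids = sorted(tids)
        if len(tids) < 2:
            continue
        m1 = mean1.loc[tids]
        m2 = mean2.loc[tids]
        if m1.max() <= active_threshold or m2.max() <= active_threshold:
            continue  # gene must be active in both groups
        primary1 = m1.sort_index().idxmax()
        primary2 = m2.sort_index().idxmax()
        if primary1 == primary2:
            continue
        if activity_delta is not None:
            shift = max(abs(m1[primary1] - m2[primary1]), abs(m1[primary2] - m2[primary2]))
            if shift < activity_delta:
                continue
        score = activity.loc[primary1] - activity.loc[primary2]
        s1 = score[g1_samples].to_numpy()
        s2 = score[g2_samples].to_numpy()
        stat, p = ranksum_pvalue(s1, s2)
        usage_diff = float(s1.mean() - s2.mean())
        if abs(usage_diff) < usage_delta:
            continue
        rows.append((gene, primary1, primary2, usage_diff, stat, p))
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "primary_group1", "primary_group2", "usage_diff", "statistic", "p"],
    )
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr_level
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------
def evaluate_regression(pred, obs, mappability=None, threshold: float = 0.75) -> dict:
    """Squared Pearson correlation and RMSE of predicted vs observed.

    With ``mappability`` given (per-promoter mean mappability), only
    promoters with mappability > ``threshold`` are evaluated.
    """
    p = np.asarray(getattr(pred, "values", pred), dtype=float)
    o = np.asarray(getattr(obs, "values", obs), dtype=float)
    if p.shape != o.shape:
        raise ValueError("prediction and observation are not aligned")
    if mappability is not None:
        keep = np.asarray(mappability, dtype=float) > threshold
        p, o = p[keep], o[keep]
    if p.size < 3:
        raise ValueError(f"only {p.size} promoters left for evaluation")
    if np.std(p) == 0 or np.std(o) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    return {"r2": r2, "rmse": rmse, "n": int(p.size)}


def expression_consistency(
    activity,
    expression: pd.DataFrame,
    gene_map: dict,
    expressed_threshold: float = 1.0,
) -> dict:
    """Gene-level consistency between promoter activity and expression.

    Gene activity is the max over the gene's promoters; it is compared
    with log2(FPKM + 1) by squared Pearson correlation, and with the
    binary label FPKM >= ``expressed_threshold`` by AUROC and average
    precision (activity as the score).  ``expression`` needs columns
    ``gene_id`` and ``fpkm``.
    """
    values = np.asarray(getattr(activity, "values", activity), dtype=float)
    tids = np.asarray(getattr(activity, "transcript_ids", np.arange(len(values))))
    df = pd.DataFrame({"transcript_id": tids, "activity": values})
    df["gene_id"] = df["transcript_id"].map(gene_map)
    gene_activity = df.dropna(subset=["gene_id"]).groupby("gene_id")["activity"].max()
    expr = expression.set_index("gene_id")["fpkm"]
    shared = gene_activity.index.intersection(expr.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between activity and expression")
    act = gene_activity.loc[shared].to_numpy()
    fpkm = expr.loc[shared].to_numpy(dtype=float)
    log_expr = np.log2(fpkm + 1.0)
    if np.std(act) == 0 or np.std(log_expr) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(act, log_expr)[0, 1] ** 2)
    labels = fpkm >= expressed_threshold
    if labels.all() or not labels.any():
        auroc = None
        avg_prec = None
    else:
        auroc = float(roc_auc_score(labels, act))
        avg_prec = float(average_precision_score(labels, act))
    return {"r2": r2, "auroc": auroc, "average_precision": avg_prec, "n_genes": int(len(shared))}


def feature_response_screen(raw: np.ndarray, response, missing: np.ndarray | None = None) -> pd.DataFrame:
    """Squared Pearson correlation of each raw feature column vs response.

    ``raw`` is the unscaled (N, scales, windows, channels) matrix.  Rows
    where a column is missing are dropped for that column.  Returns one
    row per (scale, window, channel) with the R2 and a flag for
    constant columns; the best column per scale carries ``best=True``.
    """
    y = np.asarray(getattr(response, "values", response), dtype=float)
    n, n_scales, n_windows, n_channels = raw.shape
    rows = []
    for s in range(n_scales):
        for w in range(n_windows):
            for c in range(n_channels):
                col = raw[:, s, w, c]
                ok = np.ones(n, dtype=bool) if missing is None else ~missing[:, s, w, c]
                x = col[ok]
                yy = y[ok]
                constant = x.size < 3 or np.ptp(x) == 0
                if constant or np.ptp(yy) == 0:
                    r2 = 0.0
                else:
                    r2 = float(np.corrcoef(x, yy)[0, 1] ** 2)
                rows.append((s, w, c, r2, constant))
    out = pd.DataFrame(rows, columns=["scale", "window", "channel", "r2", "constant"])
    out["best"] = False
    for s in range(n_scales):
        idx = out.loc[out["scale"] == s, "r2"].idxmax()
        out.loc[idx, "best"] = True
    return out
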