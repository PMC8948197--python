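"""IM-Index computation and the rank-based statistical battery.

The IM-Index condenses a sample's pathway fluxes into one diagnostic
score:

    IM-Index = alpha * sum(flux(P), P in signaling transduction)
             + beta  * sum(flux(P), P in energy metabolism)

with alpha = beta = 1 by default.  The remaining functions evaluate
such a score (or any competing biomarker) against group labels:
Kruskal-Wallis and Wilcoxon rank tests for group separation, midrank
Mann-Whitney AUC with stratified-bootstrap confidence intervals, a
one-sided bootstrap comparison of two classifiers' AUCs, univariate
logistic-regression odds ratios, Spearman correlation against
covariates, and per-pathway differential flux with Bonferroni
correction.

All rank statistics use midranks for ties.  Bootstrap resampling is
stratified by class (class counts are preserved in every replicate, so
the AUC is always defined) and p-values use the add-one convention
p = (1 + #extreme) / (n_boot + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from pathflux.flux import FluxMatrix


@dataclass
class IMIndexTable:
    """Per-sample IM-Index scores with the weights that produced them."""

    data: pd.DataFrame  # index sample_id; columns: im_index, group (optional)
    alpha: float = 1.0
    beta: float = 1.0

    @property
    def scores(self) -> pd.Series:
        return self.data["im_index"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, alpha: float = 1.0, beta: float = 1.0) -> "IMIndexTable":
        df = pd.read_csv(
            path, sep="\t", dtype={0: str}, float_precision="round_trip"
        ).set_index("sample_id")
        return cls(df, alpha, beta)


@dataclass
class ROCSummary:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    n_boot: int


@dataclass
class AUCComparison:
    auc_index: float
    auc_other: float
    p_one_sided: float
    n_boot: int


@dataclass
class LogisticORResult:
    """Univariate logistic fit summary; per-unit and per-SD odds ratios."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    odds_ratio_per_sd: float = math.nan
    ci_low_per_sd: float = math.nan
    ci_high_per_sd: float = math.nan
    separation: bool = False
    degenerate: bool = False


def read_labels_tsv(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read a labels TSV: sample_id, group, optional numeric biomarkers.

    Returns (sample -> group mapping, covariate DataFrame indexed by
    sample; empty if no extra columns).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.set_index("sample_id")
    labels = df["group"].to_dict()
    covariates = df.drop(columns=["group"]).apply(
        pd.to_numeric, errors="coerce"
    )
    return labels, covariates


def write_labels_tsv(
    labels: Mapping[str, str],
    path: str | Path,
    covariates: pd.DataFrame | None = None,
) -> None:
    df = pd.DataFrame({"group": pd.Series(dict(labels))})
    df.index.name = "sample_id"
    if covariates is not None:
        df = df.join(covariates)
    df.to_csv(path, sep="\t")


def compute_im_index(
    fm: FluxMatrix,
    alpha: float = 1.0,
    beta: float = 1.0,
    labels: Mapping[str, str] | None = None,
) -> IMIndexTable:
    """IM-Index per sample from a flux matrix.

    Requires every pathway to carry a class label (signaling
    transduction or energy metabolism); the two class sums are weighted
    by ``alpha`` and ``beta`` respectively.
    """
    missing = [p for p in fm.pathway_ids if p not in fm.klass_of]
    if missing:
        raise ValueError(f"pathways without a klass label: {missing}")
    sig = [p for p in fm.pathway_ids if fm.klass_of[p] == "signaling_transduction"]
    met = [p for p in fm.pathway_ids if fm.klass_of[p] == "energy_metabolism"]
    unknown = sorted(set(fm.pathway_ids) - set(sig) - set(met))
    if unknown:
        raise ValueError(f"pathways with unknown klass: {unknown}")
    index = alpha * fm.data[sig].sum(axis=1) + beta * fm.data[met].sum(axis=1)
    df = pd.DataFrame({"im_index": index})
    if labels is not None:
        df["group"] = [labels.get(s) for s in df.index]
        unlabeled = df.index[df["group"].isna()]
        if len(unlabeled):
            raise ValueError(f"samples without a group label: {list(unlabeled)}")
    return IMIndexTable(df, alpha=alpha, beta=beta)


def _align(
    scores, labels
) -> tuple[np.ndarray, np.ndarray]:
    """Align scores with labels; both mappings (joined on sample id) or
    equal-length sequences."""
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(scores, Mapping) and isinstance(labels, Mapping):
        missing = sorted(set(scores) - set(labels))
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        keys = list(scores)
        return (
            np.asarray([scores[k] for k in keys], dtype=float),
            np.asarray([labels[k] for k in keys], dtype=object),
        )
    x = np.asarray(scores, dtype=float)
    g = np.asarray(labels, dtype=object)
    if x.shape != g.shape:
        raise ValueError("scores and labels must have equal length")
    return x, g


def kruskal_wallis(scores, labels) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups (midranks, tie-corrected).

    When every observation is identical the tie correction degenerates;
    by convention that case returns H = 0, p = 1 (no evidence of any
    group difference).
    """
    x, g = _align(scores, labels)
    groups = [x[g == lev] for lev in pd.unique(g)]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    if any(len(v) == 0 for v in groups):
        raise ValueError("every group must be nonempty")
    if np.all(x == x[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_two_group(scores, labels) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for two groups.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.  Returns the
    Mann-Whitney U statistic of the first group (sorted label order)
    and the two-sided p-value.
    """
    x, g = _align(scores, labels)
    levels = sorted(map(str, pd.unique(g)))
    if len(levels) != 2:
        raise ValueError(f"wilcoxon_two_group requires exactly 2 groups, got {levels}")
    a = x[g.astype(str) == levels[0]]
    b = x[g.astype(str) == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if np.all(x == x[0]):
        return len(a) * len(b) / 2.0, 1.0
    u, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(u), float(p)


def auc_midrank(scores, y) -> float:
    """Mann-Whitney AUC with midrank tie handling: U / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    ranks = scipy.stats.rankdata(scores)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r_pos = float(np.sum(ranks[y == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _to_binary(labels, pos_label=None) -> np.ndarray:
    y = np.asarray(labels)
    levels = sorted(map(str, pd.unique(y)))
    if len(levels) != 2:
        raise ValueError(f"binary labels required, got levels {levels}")
    if pos_label is None:
        pos_label = levels[1]
    return (y.astype(str) == str(pos_label)).astype(int)


def _bootstrap_auc_rows(
    score_rows: np.ndarray, n_pos: int, n_neg: int
) -> np.ndarray:
    """Midrank AUC per row of a (n_boot, n_pos+n_neg) score array whose
    first n_pos columns are positives."""
    ranks = scipy.stats.rankdata(score_rows, axis=1)
    r_pos = ranks[:, :n_pos].sum(axis=1)
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_with_bootstrap(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | None = None,
    pos_label=None,
) -> ROCSummary:
    """Midrank AUC with a stratified percentile-bootstrap 95% CI.

    Resampling is with replacement within each class, preserving class
    counts so every replicate's AUC is defined.  Deterministic given
    ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x, g = _align(scores, labels)
    y = _to_binary(g, pos_label)
    auc = auc_midrank(x, y)
    pos = x[y == 1]
    neg = x[y == 0]
    n_pos, n_neg = len(pos), len(neg)
    rng = np.random.default_rng(seed)
    rows = np.concatenate(
        [
            pos[rng.integers(0, n_pos, size=(n_boot, n_pos))],
            neg[rng.integers(0, n_neg, size=(n_boot, n_neg))],
        ],
        axis=1,
    )
    aucs = _bootstrap_auc_rows(rows, n_pos, n_neg)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return ROCSummary(
        auc=float(auc),
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
        n_pos=n_pos,
        n_neg=n_neg,
        n_boot=n_boot,
    )


def compare_classifiers_bootstrap(
    scores_index,
    scores_other,
    labels,
    n_boot: int = 2000,
    seed: int | None = None,
    pos_label=None,
) -> AUCComparison:
    """One-sided bootstrap test that the index classifies better.

    Null hypothesis: the other score gives equal or better
    classification than the index.  Each stratified bootstrap replicate
    resamples *samples* (the same resample is scored by both
    classifiers) and computes d* = AUC_index* - AUC_other*;
    p = (1 + #{d* <= 0}) / (n_boot + 1).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    xi = np.asarray(scores_index, dtype=float)
    xo = np.asarray(scores_other, dtype=float)
    if xi.shape != xo.shape:
        raise ValueError("both classifiers must score the same samples")
    _, g = _align(xi, labels)
    y = _to_binary(g, pos_label)
    auc_i = auc_midrank(xi, y)
    auc_o = auc_midrank(xo, y)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    rng = np.random.default_rng(seed)
    idx = np.concatenate(
        [
            pos_idx[rng.integers(0, n_pos, size=(n_boot, n_pos))],
            neg_idx[rng.integers(0, n_neg, size=(n_boot, n_neg))],
        ],
        axis=1,
    )
    d = _bootstrap_auc_rows(xi[idx], n_pos, n_neg) - _bootstrap_auc_rows(
        xo[idx], n_pos, n_neg
    )
    p = (1.0 + np.sum(d <= 0.0)) / (n_boot + 1.0)
    return AUCComparison(
        auc_index=float(auc_i),
        auc_other=float(auc_o),
        p_one_sided=float(p),
        n_boot=n_boot,
    )


def logistic_odds_ratio(scores, labels, pos_label=None) -> LogisticORResult:
    """Univariate logistic regression odds ratio with 95% Wald CI.

    Samples with a missing score are dropped (complete observations
    only).  The odds ratio is per unit of the score; a per-SD odds
    ratio is reported alongside.  Complete separation and constant
    scores are flagged rather than fit.
    """
    x, g = _align(scores, labels)
    keep = np.isfinite(x)
    x, g = x[keep], g[keep]
    y = _to_binary(g, pos_label)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present after dropping missing scores")
    if np.all(x == x[0]):
        return LogisticORResult(
            odds_ratio=math.nan, ci_low=math.nan, ci_high=math.nan,
            p=math.nan, degenerate=True,
        )
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        sign = 1.0 if x[y == 1].min() > x[y == 0].max() else -1.0
        inf_or = math.inf if sign > 0 else 0.0
        return LogisticORResult(
            odds_ratio=inf_or, ci_low=math.nan, ci_high=math.nan,
            p=math.nan, separation=True,
        )

    def _fit(xv: np.ndarray) -> tuple[float, float, float, float]:
        design = sm.add_constant(xv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=False
            )
        slope = res.params[1]
        se = res.bse[1]
        return (
            math.exp(slope),
            math.exp(slope - 1.959963984540054 * se),
            math.exp(slope + 1.959963984540054 * se),
            float(res.pvalues[1]),
        )

    or_, lo, hi, p = _fit(x)
    sd = float(np.std(x, ddof=1))
    or_sd, lo_sd, hi_sd, _ = _fit(x / sd) if sd > 0 else (math.nan,) * 4
    return LogisticORResult(
        odds_ratio=or_, ci_low=lo, ci_high=hi, p=p,
        odds_ratio_per_sd=or_sd, ci_low_per_sd=lo_sd, ci_high_per_sd=hi_sd,
    )


def spearman_matrix(
    scores: IMIndexTable | pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rho of the index against each numeric covariate column.

    Columns with fewer than 3 complete (index, covariate) pairs are
    skipped with a warning.  Returns a DataFrame indexed by covariate
    with columns rho, p, n.
    """
    s = scores.scores if isinstance(scores, IMIndexTable) else scores
    rows = {}
    for col in covariates.columns:
        joined = pd.concat([s, covariates[col]], axis=1, join="inner").dropna()
        if len(joined) < 3:
            warnings.warn(
                f"covariate {col!r}: fewer than 3 complete pairs; skipped",
                stacklevel=2,
            )
            continue
        rho, p = scipy.stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
        rows[col] = {"rho": float(rho), "p": float(p), "n": len(joined)}
    return pd.DataFrame.from_dict(rows, orient="index")


def differential_pathway_flux(
    fm: FluxMatrix,
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-pathway group test with Bonferroni correction.

    Kruskal-Wallis across >= 3 groups, Wilcoxon rank-sum for exactly 2.
    p_bonferroni = min(1, p_raw * m) over the m pathways tested; rows
    are sorted by raw p ascending (ties broken by pathway id).
    """
    groups = pd.Series({s: labels[s] for s in fm.sample_ids})
    n_levels = groups.nunique()
    if n_levels < 2:
        raise ValueError("differential flux requires >= 2 groups")
    test = kruskal_wallis if n_levels >= 3 else wilcoxon_two_group
    rows = []
    for pid in fm.pathway_ids:
        stat, p = test(fm.data[pid].to_numpy(), groups.to_numpy())
        rows.append({"pathway_id": pid, "statistic": stat, "p_raw": p})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m)
    return out.sort_values(
        ["p_raw", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
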