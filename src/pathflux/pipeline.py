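"""End-to-end orchestration: expression + network + labels -> report.

``run_pipeline`` ties the stages together: load and validate inputs,
compute the flux matrix, the IM-Index, and the statistical report, and
write every artifact (flux TSV, pathway-class TSV, IM-Index TSV, stats
JSON, run-metadata JSON) into an output directory.  Runs are fully
deterministic: all randomness derives from one user seed via a
documented per-purpose splitting scheme, and every effective parameter
plus input checksums are recorded in the metadata block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import zlib
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from pathflux.flux import ExpressionMatrix, compute_flux_matrix
from pathflux.network import load_network, network_summary
from pathflux.stats import (
    compare_classifiers_bootstrap,
    compute_im_index,
    differential_pathway_flux,
    kruskal_wallis,
    logistic_odds_ratio,
    read_labels_tsv,
    roc_with_bootstrap,
    spearman_matrix,
    wilcoxon_two_group,
)

logger = logging.getLogger(__name__)

#: positive class per contrast, by convention: the more-progressed group
_GROUP_SEVERITY = {"control": 0, "benign": 1, "malignant": 2}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; recorded in run metadata."""

    network: str | Path
    expression: str | Path
    labels: str | Path
    out_dir: str | Path
    alpha: float = 1.0
    beta: float = 1.0
    n_boot: int = 2000
    seed: int = 0
    missing_floor: float = 0.0
    scale: float = 1.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        for name in ("alpha", "beta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("network", "expression", "labels"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def child_seed(seed: int, purpose: str) -> int:
    """Per-purpose child seed: SeedSequence keyed by (seed, crc32(purpose)).

    Distinct purposes give independent streams; the result is < 2**31
    so it can be passed anywhere a small seed is expected.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(purpose.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def _jsonify(obj):
    """Recursively make JSON-serializable; floats at 12 significant digits."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "Infinity" if x > 0 else "-Infinity"
        return _round_sig(x)
    return obj


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _pos_neg(g1: str, g2: str) -> tuple[str, str]:
    """Order a group pair as (positive, negative) by disease severity,
    falling back to reverse-lexicographic for unknown labels."""
    key = lambda g: (_GROUP_SEVERITY.get(g, -1), g)
    pos, neg = sorted((g1, g2), key=key, reverse=True)
    return pos, neg


def primary_contrast(groups: list[str]) -> tuple[str, str] | None:
    """The headline two-group comparison: malignant vs benign when both
    exist, otherwise the most severe pair, or None with < 2 groups."""
    if {"malignant", "benign"} <= set(groups):
        return "malignant", "benign"
    if len(groups) < 2:
        return None
    key = lambda g: (_GROUP_SEVERITY.get(g, -1), g)
    top = sorted(groups, key=key, reverse=True)[:2]
    return _pos_neg(top[0], top[1])


def build_stats_report(
    fm,
    labels: dict[str, str],
    covariates: pd.DataFrame | None = None,
    alpha: float = 1.0,
    beta: float = 1.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Assemble the full statistics report from a flux matrix.

    Sections: ``im_index`` (per-group medians and weights),
    ``group_tests`` (Kruskal-Wallis across all groups, pairwise
    Wilcoxon), ``roc`` (bootstrap AUC for every group pair),
    ``comparisons`` (index vs each biomarker: AUC comparison and
    logistic odds ratios, on the primary contrast), ``spearman`` and
    ``differential_flux``.
    """
    table = compute_im_index(fm, alpha=alpha, beta=beta, labels=labels)
    scores = table.scores
    groups = table.data["group"]
    levels = sorted(groups.unique())

    report: dict = {
        "im_index": {
            "alpha": alpha,
            "beta": beta,
            "n_samples": int(len(scores)),
            "median_by_group": {
                g: float(scores[groups == g].median()) for g in levels
            },
        }
    }

    group_tests: dict = {}
    if len(levels) >= 2:
        h, p = kruskal_wallis(scores.to_numpy(), groups.to_numpy())
        group_tests["kruskal_wallis"] = {"H": h, "p": p, "n_groups": len(levels)}
        pairwise = {}
        for g1, g2 in combinations(levels, 2):
            mask = groups.isin([g1, g2])
            w, p = wilcoxon_two_group(
                scores[mask].to_numpy(), groups[mask].to_numpy()
            )
            pairwise[f"{g1}_vs_{g2}"] = {"W": w, "p": p}
        group_tests["wilcoxon_pairwise"] = pairwise
    report["group_tests"] = group_tests

    roc: dict = {}
    for g1, g2 in combinations(levels, 2):
        pos, neg = _pos_neg(g1, g2)
        mask = groups.isin([pos, neg])
        summary = roc_with_bootstrap(
            scores[mask].to_numpy(),
            groups[mask].to_numpy(),
            n_boot=n_boot,
            seed=child_seed(seed, f"roc:{pos}:{neg}"),
            pos_label=pos,
        )
        roc[f"{pos}_vs_{neg}"] = dataclasses.asdict(summary)
    report["roc"] = roc

    comparisons: dict = {}
    contrast = primary_contrast(levels)
    if contrast is not None:
        pos, neg = contrast
        mask = groups.isin([pos, neg])
        y = groups[mask]
        x_index = scores[mask]
        comparisons["contrast"] = {"positive": pos, "negative": neg}
        comparisons["logistic_index"] = dataclasses.asdict(
            logistic_odds_ratio(x_index.to_numpy(), y.to_numpy(), pos_label=pos)
        )
        if covariates is not None and len(covariates.columns):
            biomarkers = {}
            for col in covariates.columns:
                cov = covariates[col].reindex(x_index.index)
                complete = cov.notna()
                if complete.sum() < 3 or y[complete].nunique() < 2:
                    continue
                cmp_res = compare_classifiers_bootstrap(
                    x_index[complete].to_numpy(),
                    cov[complete].to_numpy(),
                    y[complete].to_numpy(),
                    n_boot=n_boot,
                    seed=child_seed(seed, f"compare:{col}"),
                    pos_label=pos,
                )
                biomarkers[col] = {
                    "auc_comparison": dataclasses.asdict(cmp_res),
                    "logistic": dataclasses.asdict(
                        logistic_odds_ratio(
                            cov[complete].to_numpy(),
                            y[complete].to_numpy(),
                            pos_label=pos,
                        )
                    ),
                }
            comparisons["biomarkers"] = biomarkers
    report["comparisons"] = comparisons

    if covariates is not None and len(covariates.columns):
        report["spearman"] = {
            col: row.to_dict()
            for col, row in spearman_matrix(table, covariates).iterrows()
        }
    else:
        report["spearman"] = {}

    if len(levels) >= 2:
        diff = differential_pathway_flux(fm, labels)
        report["differential_flux"] = diff.to_dict(orient="records")
    else:
        report["differential_flux"] = []

    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the stats report."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = load_network(cfg.network)
    mat = ExpressionMatrix.from_tsv(cfg.expression)
    labels, covariates = read_labels_tsv(cfg.labels)
    unlabeled = sorted(set(mat.sample_ids) - set(labels))
    if unlabeled:
        raise ValueError(f"samples without a group label: {unlabeled}")

    fm = compute_flux_matrix(
        mat, net, missing_floor=cfg.missing_floor, scale=cfg.scale
    )
    fm.to_tsv(out / "flux_matrix.tsv", out / "pathway_klass.tsv")

    table = compute_im_index(fm, alpha=cfg.alpha, beta=cfg.beta, labels=labels)
    table.to_tsv(out / "im_index.tsv")

    report = build_stats_report(
        fm,
        labels,
        covariates=covariates,
        alpha=cfg.alpha,
        beta=cfg.beta,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
    )
    (out / "stats.json").write_text(
        json.dumps(_jsonify(report), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    metadata = {
        "config": {
            "network": str(cfg.network),
            "expression": str(cfg.expression),
            "labels": str(cfg.labels),
            "out_dir": str(cfg.out_dir),
            "alpha": cfg.alpha,
            "beta": cfg.beta,
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
            "missing_floor": cfg.missing_floor,
            "scale": cfg.scale,
            "log_level": cfg.log_level,
        },
        "seed_scheme": "SeedSequence([seed, crc32(purpose)]) per purpose",
        "input_sha256": {
            "network": _sha256(cfg.network),
            "expression": _sha256(cfg.expression),
            "labels": _sha256(cfg.labels),
        },
        "network_summary": network_summary(net),
    }
    (out / "run_metadata.json").write_text(
        json.dumps(_jsonify(metadata), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    logger.info("pipeline finished; artifacts in %s", out)
    return report
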