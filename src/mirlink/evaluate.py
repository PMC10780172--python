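"""Cross-validation driver, ablation grid, and candidate ranking.

The protocol: sample negatives once over the full unknown set (equal in
number to the positives by default), partition positives and negatives into
k stratified folds, and for each fold

1. mask the fold's positives out of the association matrix,
2. rebuild every graph view from the masked matrix (leakage control: the
   encoders never see a held-out association),
3. train the full model on the remaining labeled pairs,
4. score the held-out fold.

Candidate ranking scores every miRNA against a query disease, removes pairs
already known, and returns the top-k by predicted probability (ties broken
by miRNA index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .data import AssociationDataset, FoldSplit, kfold_split, mask_test_edges, sample_negatives
from .metrics import MetricReport, compute_metrics
from .model import MultiViewLinkModel, MultiViewLinkResults, TrainConfig

__all__ = ["CVResult", "RankingResult", "run_cross_validation", "ablation_grid",
           "rank_candidates"]

_METRIC_COLS = ["auc", "aupr", "accuracy", "precision", "recall", "f1"]


@dataclass
class CVResult:
    """Per-fold metric reports plus the fold split that produced them."""

    reports: list[MetricReport]
    split: FoldSplit
    config: TrainConfig

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.as_dict() for r in self.reports])
        df.insert(0, "fold", range(1, len(self.reports) + 1))
        return df

    def mean(self) -> dict:
        return {c: float(self.frame[c].mean()) for c in _METRIC_COLS}

    def std(self) -> dict:
        return {c: float(self.frame[c].std(ddof=1)) for c in _METRIC_COLS}

    def summary(self) -> str:
        mean, std = self.mean(), self.std()
        lines = [f"{self.split.k}-fold cross-validation "
                 f"(views: {', '.join(self.config.views)}, attention: "
                 f"{'on' if self.config.use_cascade_attention else 'off'})"]
        for c in _METRIC_COLS:
            lines.append(f"  {c:<10} {mean[c]:.4f} +- {std[c]:.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.split.k, "seed": self.split.seed,
             "folds": [{k: round(v, 6) for k, v in r.as_dict().items()}
                       for r in self.reports],
             "mean": {k: round(v, 6) for k, v in self.mean().items()},
             "std": {k: round(v, 6) for k, v in self.std().items()}},
            sort_keys=True, indent=2)


@dataclass
class RankingResult:
    """Ranked candidate miRNAs for one disease, known associations removed."""

    disease: str
    mirnas: list[str]
    scores: list[float]
    top_k: int

    def to_tsv(self) -> str:
        lines = ["rank\tmiRNA\tscore"]
        for r, (name, s) in enumerate(zip(self.mirnas, self.scores), start=1):
            lines.append(f"{r}\t{name}\t{s:.6f}")
        return "\n".join(lines) + "\n"


def run_cross_validation(
    ds: AssociationDataset,
    config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    neg_ratio: float = 1.0,
    return_results: bool = False,
):
    """Stratified k-fold cross-validation with per-fold view masking."""
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or TrainConfig()
    pos = ds.positive_pairs()
    neg = sample_negatives(ds, ratio=neg_ratio, seed=seed)
    split = kfold_split(pos, neg, k, seed=seed)
    reports, fitted = [], []
    for fold in range(k):
        train, test = split.train_test(fold)
        test_pos = [(i, j) for i, j, lab in test if lab == 1]
        masked = mask_test_edges(ds, test_pos)
        model = MultiViewLinkModel(
            masked,
            [(i, j) for i, j, _ in train],
            [lab for _, _, lab in train],
            config,
        )
        res = model.fit()
        probs = res.predict([(i, j) for i, j, _ in test])
        labels = [lab for _, _, lab in test]
        reports.append(compute_metrics(labels, probs))
        if return_results:
            fitted.append(res)
    cv = CVResult(reports=reports, split=split, config=config)
    return (cv, fitted) if return_results else cv


def ablation_grid(
    ds: AssociationDataset,
    config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    view_subsets=None,
) -> pd.DataFrame:
    """Cross-validate every view subset with and without cascade attention.

    Returns one row per (view subset, attention) cell with mean metrics —
    the structure of the published ablation table.
    """
    from dataclasses import replace

    config = config or TrainConfig()
    if view_subsets is None:
        all_views = ("local", "global", "semantic")
        view_subsets = [
            tuple(v for i, v in enumerate(all_views) if (mask >> i) & 1)
            for mask in range(1, 8)
        ]
    rows = []
    for attention in (True, False):
        for views in view_subsets:
            cfg = replace(config, views=tuple(views),
                          use_cascade_attention=attention)
            cv = run_cross_validation(ds, cfg, k=k, seed=seed)
            row = {"views": "+".join(views),
                   "attention": "with" if attention else "without"}
            row.update({c: round(v, 4) for c, v in cv.mean().items()})
            rows.append(row)
    return pd.DataFrame(rows)


def rank_candidates(
    results: MultiViewLinkResults,
    ds: AssociationDataset,
    disease: str,
    top_k: int = 30,
) -> RankingResult:
    """Top-k candidate miRNAs for a disease, excluding known associations."""
    j = ds.disease_index(disease)
    scores = results.predict([(i, j) for i in range(ds.m)])
    candidates = [i for i in range(ds.m) if ds.A[i, j] == 0]
    # stable sort on -score keeps miRNA-index order among ties
    order = sorted(candidates, key=lambda i: (-scores[i], i))[:top_k]
    return RankingResult(
        disease=disease,
        mirnas=[ds.mirna_names[i] for i in order],
        scores=[float(scores[i]) for i in order],
        top_k=top_k,
    )
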