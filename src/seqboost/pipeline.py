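"""End-to-end orchestration: featurize, select, train, evaluate, rank."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import gbdt, kgap, mappings, selection as fsel
from .errors import ConfigError, DataLeakError
from .evaluation import CVPlan, MetricsReport, average_reports, cross_validate
from .features import FeatureSchema, matrix_from_vectors
from .io import FastaDataset


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, hashable for provenance."""

    family: str = "pyfeat"  # pyfeat | rff | both
    kgap_n: int = 5
    pseudo_K: int = 3
    normalize_counts: bool = False
    selection_rounds: int = 50
    selection_depth: int = 1
    selection_rule: str = "nonzero"
    selection_top_k: Optional[int] = None
    select_in_fold: bool = True
    gbdt_rounds: int = 100
    gbdt_lr: float = 0.1
    gbdt_max_depth: int = 3
    gbdt_min_leaf: int = 5
    cv_folds: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def gbdt_params(self) -> dict:
        return dict(
            rounds=self.gbdt_rounds,
            lr=self.gbdt_lr,
            max_depth=self.gbdt_max_depth,
            min_leaf=self.gbdt_min_leaf,
            seed=self.seed,
        )

    def selection_params(self) -> dict:
        return dict(
            rounds=self.selection_rounds,
            depth=self.selection_depth,
            seed=self.seed,
        )


def featurize_dataset(
    ds: FastaDataset, cfg: PipelineConfig
) -> tuple[FeatureSchema, pd.DataFrame]:
    """Feature matrix for every record, per the configured family."""
    if cfg.family not in ("pyfeat", "rff", "both"):
        raise ConfigError(f"unknown feature family {cfg.family!r}")
    vectors = []
    pyfeat_schema = kgap.build_schema(cfg.pseudo_K, cfg.kgap_n)
    for rec in ds.records:
        parts = []
        if cfg.family in ("pyfeat", "both"):
            parts.append(
                kgap.pyfeat_vector(
                    rec,
                    K=cfg.pseudo_K,
                    n=cfg.kgap_n,
                    normalize=cfg.normalize_counts,
                    schema=pyfeat_schema,
                ).values
            )
        if cfg.family in ("rff", "both"):
            parts.append(mappings.rff_vector(rec).values)
        vectors.append((rec.id, np.concatenate(parts)))
    blocks = []
    if cfg.family in ("pyfeat", "both"):
        blocks.extend(pyfeat_schema.blocks)
    if cfg.family in ("rff", "both"):
        blocks.extend(mappings.rff_schema().blocks)
    schema = FeatureSchema(tuple(blocks))
    data = np.vstack([v for _, v in vectors])
    return schema, pd.DataFrame(
        data, index=[i for i, _ in vectors], columns=schema.names
    )


def evaluate_two_class(
    X: np.ndarray, y: np.ndarray, cfg: PipelineConfig
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold CV of the select+train pipeline on one matrix."""
    plan = CVPlan(k=cfg.cv_folds, seed=cfg.seed)
    selection_params = cfg.selection_params() if cfg.select_in_fold else None
    if not cfg.select_in_fold:
        X = fsel.impute_missing(X)
        ranking = fsel.fit_importance(X, y, **cfg.selection_params())
        mask = fsel.select(ranking, rule=cfg.selection_rule, k=cfg.selection_top_k)
        if mask.selected_count:
            X = X[:, mask.keep]
    return cross_validate(
        X,
        y,
        plan,
        gbdt_params=cfg.gbdt_params(),
        selection_params=selection_params,
    )


def batch_evaluate(
    pos: FastaDataset,
    neg_batches: list[FastaDataset],
    cfg: PipelineConfig,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Pair the positive set with each negative batch, cross-validate each
    balanced two-class set, and average the per-batch reports."""
    if not neg_batches:
        raise ValueError("need at least one negative batch")
    pos_ids = set(pos.ids())
    batch_reports: list[MetricsReport] = []
    for batch in neg_batches:
        overlap = pos_ids & set(batch.ids())
        if overlap:
            raise DataLeakError(
                f"ids shared between positives and batch {batch.source!r}: "
                f"{sorted(overlap)[:5]}"
            )
        combined = FastaDataset(
            records=list(pos.with_label(1).records) + list(batch.with_label(0).records),
            source=f"{pos.source}+{batch.source}",
        )
        _, X = featurize_dataset(combined, cfg)
        y = np.array([r.label for r in combined.records], dtype=int)
        report, _ = evaluate_two_class(X.to_numpy(), y, cfg)
        batch_reports.append(report)
    return average_reports(batch_reports), batch_reports


def train_full(
    pos: FastaDataset, neg: FastaDataset, cfg: PipelineConfig
) -> tuple[gbdt.GBDTModel, fsel.SelectionMask, FeatureSchema]:
    """Fit selection + GBDT on all labeled data (for ranking new queries)."""
    combined = FastaDataset(
        records=list(pos.with_label(1).records) + list(neg.with_label(0).records),
        source="training",
    )
    schema, X_df = featurize_dataset(combined, cfg)
    X = fsel.impute_missing(X_df.to_numpy())
    y = np.array([r.label for r in combined.records], dtype=int)
    ranking = fsel.fit_importance(X, y, **cfg.selection_params())
    mask = fsel.select(ranking, rule=cfg.selection_rule, k=cfg.selection_top_k)
    X_sel = X[:, mask.keep] if mask.selected_count else X
    model = gbdt.train(X_sel, y, **cfg.gbdt_params())
    return model, mask, schema


def rank_candidates(
    model: gbdt.GBDTModel,
    mask: fsel.SelectionMask,
    queries: FastaDataset,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Probability-ranked table for unlabeled query records (descending
    probability, ties broken by id)."""
    _, X_df = featurize_dataset(queries, cfg)
    X = fsel.impute_missing(X_df.to_numpy())
    if mask.selected_count:
        X = X[:, mask.keep]
    proba = gbdt.predict_proba(model, X)
    table = pd.DataFrame({"id": X_df.index, "probability": proba})
    return table.sort_values(
        ["probability", "id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def report_to_dict(report: MetricsReport, cfg: PipelineConfig) -> dict:
    out = report.as_dict()
    out["flags"] = sorted(report.flags)
    out["config_hash"] = cfg.config_hash()
    out["config"] = asdict(cfg)
    return out
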