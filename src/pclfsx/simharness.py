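"""Simulation harness: replicate RFE vs PCLFS vs PCLFS-ext experiments across
imbalance rates, sample sizes, classifiers and SMOTE on/off, and aggregate.

Each replicate generates a dataset with a known informative mask, splits it
75/25 stratified, optionally rebalances the training part with SMOTE, runs
the three methods on the shared data and scores both the final model (F1,
error rate) and the selection itself (TPR_fs, correct percentage, subset
size). Per-replicate seeds are base_seed + replicate index so partial reruns
reproduce.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._classifiers import make_classifier
from .datagen import Dataset, SmoteConfig, SynthSpec, generate_dataset, smote, split
from .metrics import SelectionMetrics, correct_pct, error_rate, f1_score, tpr_fs
from .ranking import rfe_select
from .selection import run_pclfs_ext

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationScenario",
    "run_replicate",
    "run_scenario",
    "report",
    "METHODS",
]

METHODS = ("RFE", "PCLFS", "PCLFS-ext")


@dataclass
class SimulationScenario:
    """One simulated experimental cell (sweeping n_informative)."""

    n_samples: int = 1000
    n_features: int = 30
    n_informative_sweep: tuple[int, ...] = (10,)
    imbalance: tuple[float, float] = (0.5, 0.5)
    class_sep: float = 1.0
    classifier_id: str = "logit"
    use_smote: bool = False
    T: float = 0.05
    test_fraction: float = 0.25
    replicates: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(k > self.n_features for k in self.n_informative_sweep):
            raise ValueError("sweep values must not exceed n_features")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _fit_and_score(train: Dataset, test: Dataset, cols, classifier_id, seed) -> tuple[float, float]:
    cols = np.asarray(cols, dtype=int)
    model = make_classifier(classifier_id, seed=seed)
    model.fit(train.X[:, cols], train.y)
    pred = model.predict(test.X[:, cols])
    return f1_score(test.y, pred), error_rate(test.y, pred)


def run_replicate(
    scenario: SimulationScenario, n_informative: int, rep_seed: int
) -> dict[str, SelectionMetrics]:
    """Generate one dataset and run all three methods on the shared split."""
    spec = SynthSpec(
        n_samples=scenario.n_samples,
        n_features=scenario.n_features,
        n_informative=n_informative,
        class_weights=scenario.imbalance,
        class_sep=scenario.class_sep,
        seed=rep_seed,
    )
    ds = generate_dataset(spec)
    train, test = split(ds, test_fraction=scenario.test_fraction, stratify=True, seed=rep_seed)
    if scenario.use_smote:
        train = smote(train, SmoteConfig(seed=rep_seed))
    informative = ds.informative_indices
    n = ds.n_features

    records: dict[str, SelectionMetrics] = {}

    rfe_idx = rfe_select(train, scenario.classifier_id, seed=rep_seed)
    f1, err = _fit_and_score(train, test, rfe_idx, scenario.classifier_id, rep_seed)
    records["RFE"] = SelectionMetrics(
        f1=f1,
        error_rate=err,
        tpr_fs=tpr_fs(rfe_idx, informative),
        correct_pct=correct_pct(rfe_idx, informative, n),
        n_selected=len(rfe_idx),
    )

    pclfs_res, ext_res = run_pclfs_ext(
        train, test, classifier_id=scenario.classifier_id, T=scenario.T, seed=rep_seed
    )
    pclfs_idx = pclfs_res.selected
    records["PCLFS"] = SelectionMetrics(
        f1=pclfs_res.f1,
        error_rate=_fit_and_score(train, test, pclfs_idx, scenario.classifier_id, rep_seed)[1],
        tpr_fs=tpr_fs(pclfs_idx, informative),
        correct_pct=correct_pct(pclfs_idx, informative, n),
        n_selected=int(pclfs_res.n_pclfs),
    )
    records["PCLFS-ext"] = SelectionMetrics(
        f1=float(ext_res.f1_at_proposed),
        error_rate=_fit_and_score(train, test, ext_res.subset, scenario.classifier_id, rep_seed)[1],
        tpr_fs=tpr_fs(ext_res.subset, informative),
        correct_pct=correct_pct(ext_res.subset, informative, n),
        n_selected=int(ext_res.n_proposed),
    )
    return records


def run_scenario(scenario: SimulationScenario, raw_path: str | Path | None = None) -> pd.DataFrame:
    """Aggregate replicates into a tidy table keyed by (method, n_informative).

    Degenerate replicates (a class missing from a split) are skipped with a
    warning and excluded from the denominators; the skip count is logged.
    Returns the summary frame; raw per-replicate records are optionally
    written as TSV.
    """
    raw_rows = []
    for k in scenario.n_informative_sweep:
        skipped = 0
        for rep in range(scenario.replicates):
            rep_seed = scenario.base_seed + rep
            try:
                records = run_replicate(scenario, k, rep_seed)
            except ValueError as exc:
                skipped += 1
                logger.warning("replicate %d (k=%d) skipped: %s", rep, k, exc)
                continue
            for method, m in records.items():
                raw_rows.append({"n_informative": k, "replicate": rep, "method": method, **asdict(m)})
        if skipped:
            logger.warning("k=%d: %d/%d replicates skipped", k, skipped, scenario.replicates)
    raw = pd.DataFrame(raw_rows)
    if raw_path is not None:
        raw.to_csv(raw_path, sep="\t", index=False)

    if raw.empty:
        return pd.DataFrame(
            columns=[
                "method", "n_informative", "mean_f1", "mean_n_selected", "mean_tpr_fs",
                "mean_correct_pct", "best_error_rate", "mean_error_rate", "sd_error_rate",
                "n_replicates",
            ]
        )
    grp = raw.groupby(["method", "n_informative"], sort=True)
    summary = grp.agg(
        mean_f1=("f1", "mean"),
        mean_n_selected=("n_selected", "mean"),
        mean_tpr_fs=("tpr_fs", "mean"),
        mean_correct_pct=("correct_pct", "mean"),
        best_error_rate=("error_rate", "min"),
        mean_error_rate=("error_rate", "mean"),
        sd_error_rate=("error_rate", lambda s: float(s.std(ddof=1)) if len(s) > 1 else 0.0),
        n_replicates=("replicate", "count"),
    ).reset_index()
    return summary


def report(summary: pd.DataFrame, out_dir: str | Path, stem: str = "summary") -> list[Path]:
    """Write the summary as TSV and JSON; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    js = out_dir / f"{stem}.json"
    summary.to_csv(tsv, sep="\t", index=False)
    js.write_text(json.dumps(summary.to_dict(orient="records"), indent=2))
    return [tsv, js]
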