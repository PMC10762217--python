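"""End-to-end orchestration and the accuracy-by-missing-rate evaluation protocol.

``run_pipeline`` goes from an observed masked matrix to per-cell mechanism calls
without ever seeing generating parameters or labels: pan the missingness left,
optionally apply the 80% rule, extract the maximal complete subset, search the
tier thresholds and MNAR share by PSO, simulate a labeled training set at those
parameters, train the classifier, and predict every missing cell.

``evaluate_protocol`` wraps that pipeline in the benchmark loop: simulate ground
truth at each (alpha, missing rate) from a complete matrix via the mean-based
tier rule, run the pipeline blind, and score predicted vs true mechanisms.
Labels enter only the scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import MNAR, AbundanceMatrix, MaskedMatrix, MissingnessSpec, ThresholdParams
from .classifier import TrainedClassifier, predict, train
from .feature_extraction import FeatureTable, build_training_set, extract_features
from .mm_simulator import simulate_mm, tier_by_mean_rule, tier_by_percent
from .panning import eighty_percent_filter, max_complete_subset, pan_left
from .threshold_search import PSOConfig, SearchResult, missing_rate_vector, pso_search


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sub_seed(*parts: int) -> int:
    return int(np.random.SeedSequence([int(p) for p in parts]).generate_state(1)[0])


@dataclass(frozen=True)
class PipelineConfig:
    backend: str = "xgb"
    pso: PSOConfig = field(default_factory=PSOConfig)
    n_training_copies: int = 5
    split: float = 0.8
    apply_80_rule: bool | None = None  # None = auto when the subset would be narrow
    min_subset_width: int = 10
    seed: int = 0


@dataclass
class PipelineResult:
    search: SearchResult
    model: TrainedClassifier
    calls: pd.DataFrame  # metabolite_id, sample_id, predicted_mechanism
    validation_accuracy: float
    complete_subset: AbundanceMatrix
    rate: float


def _restrict_rows(masked: MaskedMatrix, keep_ids: list[str]) -> MaskedMatrix:
    pos = {mid: i for i, mid in enumerate(masked.metabolite_ids)}
    idx = np.array([pos[mid] for mid in keep_ids], dtype=int)
    return MaskedMatrix(
        metabolite_ids=list(keep_ids),
        sample_ids=list(masked.sample_ids),
        values=masked.values[idx],
        mask=masked.mask[idx],
    )


class _ConstantEstimator:
    """Degenerate estimator used when training labels are single-class."""

    def __init__(self, code: int):
        self.code = int(code)

    def predict(self, X):
        return np.full(len(X), self.code, dtype=int)


def _constant_classifier(mechanism: str, training, config: PipelineConfig) -> TrainedClassifier:
    from .classifier import CLASS_ORDER

    return TrainedClassifier(
        backend=f"constant-{mechanism.lower()}",
        model=_ConstantEstimator(CLASS_ORDER.index(mechanism)),
        metabolite_codes=dict(training.metabolite_codes),
        classes=CLASS_ORDER,
        seed=config.seed,
        split=config.split,
        hyperparams={},
    )


def _predict_all_cells(
    masked: MaskedMatrix, params: ThresholdParams, model: TrainedClassifier
) -> pd.DataFrame:
    """Mechanism calls for every missing cell of ``masked``.

    Prediction-time tiers apply the searched (x, y, z) to the observed-mean
    ranking of the matrix — the only label-free option.  Metabolites with no
    observed value at all have undefined feature statistics; they are the
    extreme left-censoring signature and are called MNAR directly.
    """
    full_rows = masked.mask.all(axis=1)
    fallback_calls = []
    for i in np.nonzero(full_rows)[0]:
        for j in range(len(masked.sample_ids)):
            fallback_calls.append(
                (masked.metabolite_ids[int(i)], masked.sample_ids[j], MNAR)
            )
    frames = []
    if fallback_calls:
        frames.append(
            pd.DataFrame(
                fallback_calls,
                columns=["metabolite_id", "sample_id", "predicted_mechanism"],
            )
        )
    keep_ids = [
        mid for i, mid in enumerate(masked.metabolite_ids) if not full_rows[i]
    ]
    sub = _restrict_rows(masked, keep_ids) if fallback_calls else masked
    if sub.n_missing > 0:
        pred_tiers = tier_by_percent(sub, params)
        feats = extract_features(sub, pred_tiers, metabolite_codes=model.metabolite_codes)
        calls = feats.frame[["metabolite_id", "sample_id"]].copy()
        calls["predicted_mechanism"] = predict(model, feats).to_numpy()
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(masked: MaskedMatrix, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Classify every missing cell of ``masked`` as MNAR or MCAR."""
    if masked.n_missing == 0:
        raise PipelineError("pipeline: nothing to classify (no missing cells)")
    work = masked
    try:
        width_now = int((~pan_left(work).mask).sum(axis=1).min())
        apply_rule = (
            config.apply_80_rule
            if config.apply_80_rule is not None
            else width_now < config.min_subset_width
        )
        if apply_rule:
            work = eighty_percent_filter(work)
        complete = max_complete_subset(pan_left(work))
    except Exception as exc:
        raise PipelineError(f"panning/subset stage: {exc}") from exc

    observed = _restrict_rows(masked, complete.metabolite_ids)
    target = missing_rate_vector(observed)
    rate = observed.missing_rate
    try:
        search = pso_search(
            complete,
            target,
            rate,
            config=replace(config.pso, seed=_sub_seed(config.seed, 1)),
        )
    except Exception as exc:
        raise PipelineError(f"threshold search stage: {exc}") from exc

    try:
        training = build_training_set(
            complete,
            search.best,
            rate,
            n_copies=config.n_training_copies,
            seed=_sub_seed(config.seed, 2),
        )
        present = training.labels.dropna().unique()
        if len(present) >= 2:
            model, val_acc = train(
                training,
                backend=config.backend,
                split=config.split,
                seed=_sub_seed(config.seed, 3) % (2**31),
            )
        else:
            # searched alpha at an extreme: the simulated training set carries a
            # single mechanism, so the classifier degenerates to that constant
            model = _constant_classifier(str(present[0]), training, config)
            val_acc = 1.0
    except Exception as exc:
        raise PipelineError(f"training stage: {exc}") from exc

    try:
        calls = _predict_all_cells(masked, search.best, model)
    except Exception as exc:
        raise PipelineError(f"prediction stage: {exc}") from exc

    return PipelineResult(
        search=search,
        model=model,
        calls=calls,
        validation_accuracy=val_acc,
        complete_subset=complete,
        rate=rate,
    )


@dataclass
class EvaluationReport:
    """Long-format per-run accuracies plus per-missing-rate means."""

    frame: pd.DataFrame  # alpha, rate, batch, accuracy, majority_rate, n_missing
    backend: str
    seed: int

    def rate_means(self) -> pd.DataFrame:
        out = (
            self.frame.groupby("rate", as_index=False)["accuracy"]
            .mean()
            .rename(columns={"accuracy": "mean_accuracy"})
        )
        return out

    def alpha_rate_means(self) -> pd.DataFrame:
        return (
            self.frame.groupby(["alpha", "rate"], as_index=False)["accuracy"]
            .mean()
            .rename(columns={"accuracy": "mean_accuracy"})
        )


def score_calls(masked_truth: MaskedMatrix, calls: pd.DataFrame) -> tuple[float, float]:
    """(accuracy, majority-class rate) of predicted vs true mechanisms."""
    truth = masked_truth.labels_frame().rename(columns={"mechanism": "true_mechanism"})
    merged = truth.merge(calls, on=["metabolite_id", "sample_id"], how="left")
    if merged["predicted_mechanism"].isna().any():
        raise ValueError("calls do not cover every missing cell")
    accuracy = float((merged.true_mechanism == merged.predicted_mechanism).mean())
    majority = float(merged.true_mechanism.value_counts(normalize=True).max())
    return accuracy, majority


def evaluate_protocol(
    complete: AbundanceMatrix,
    alphas: tuple[float, ...] = (0.4, 0.45, 0.5, 0.55, 0.6),
    rates: tuple[float, ...] = tuple(np.round(np.arange(0.025, 0.401, 0.025), 4)),
    n_batches: int = 10,
    backend: str = "xgb",
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Accuracy-by-missing-rate benchmark on simulated ground truth.

    For each (alpha, rate, batch): simulate a labeled masked matrix from
    ``complete`` using the mean-based tier rule, run the pipeline blind to the
    generating parameters, and score the calls against the true mechanisms.
    """
    truth_tiers = tier_by_mean_rule(complete)
    base = config or PipelineConfig(backend=backend)
    rows = []
    for ia, alpha in enumerate(alphas):
        for ir, rate in enumerate(rates):
            if not 0.0 < rate < 1.0:
                raise ValueError(f"rates must lie in (0, 1), got {rate}")
            for batch in range(n_batches):
                run_seed = _sub_seed(seed, ia, ir, batch)
                spec = MissingnessSpec(
                    rate=rate,
                    params=ThresholdParams(x=0.0, y=0.0, z=100.0, alpha=alpha),
                    seed=run_seed,
                )
                truth = simulate_mm(complete, truth_tiers, spec)
                blind = MaskedMatrix(  # strip the labels before the pipeline sees it
                    metabolite_ids=list(truth.metabolite_ids),
                    sample_ids=list(truth.sample_ids),
                    values=truth.values,
                    mask=truth.mask,
                )
                result = run_pipeline(
                    blind, replace(base, backend=backend, seed=_sub_seed(run_seed, 7))
                )
                accuracy, majority = score_calls(truth, result.calls)
                rows.append(
                    (alpha, rate, batch, accuracy, majority, truth.n_missing)
                )
    frame = pd.DataFrame(
        rows,
        columns=["alpha", "rate", "batch", "accuracy", "majority_rate", "n_missing"],
    )
    return EvaluationReport(frame=frame, backend=backend, seed=seed)


def plot_report(report: EvaluationReport, path: str) -> None:
    """Accuracy-vs-missing-rate line plot (one line per alpha); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for alpha, grp in report.alpha_rate_means().groupby("alpha"):
        ax.plot(grp["rate"], grp["mean_accuracy"], marker="o", label=f"alpha={alpha}")
    ax.set_xlabel("missing rate")
    ax.set_ylabel("mean accuracy")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
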