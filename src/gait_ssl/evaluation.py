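"""Evaluation battery: error metrics, peak/valley analysis, percent
improvements, data-efficiency curves, cross-joint matrices, and multi-seed
aggregation.

MSE and MAE follow the standard definitions

    MSE = (1/N) Σ (y_i − ŷ_i)²        MAE = (1/N) Σ |y_i − ŷ_i|

over all samples of a test set, per joint, with moments in N·m/kg. The
multi-run protocol reports the mean over independently seeded training
runs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import IncompleteResultError, InvalidArgumentError, SchemaError
from .model import TransformerAutoencoder
from .preprocess import WindowSet
from .synthetic import JOINT_ORDER, MOMENT_CHANNELS, SAGITTAL_ANGLES
from .training import FinetuneSpec, PretrainSpec, _eval_supervised, finetune, train_baseline

# Published per-joint test MSEs ((N·m/kg)²) for the pediatric treadmill
# cohort this package models: (baseline, SSL fine-tuned), full labels.
REFERENCE_MSE_PAIRS: dict[str, tuple[float, float]] = {
    "LKneeFlex": (0.047, 0.032),
    "RKneeFlex": (0.045, 0.025),
    "LAnkleFlex": (0.018, 0.011),
    "RAnkleFlex": (0.018, 0.012),
    "LHipFlex": (0.031, 0.017),
    "RHipFlex": (0.025, 0.019),
}
# Published right-knee MAE pair (N·m/kg) and the 50%-label efficiency pair.
REFERENCE_RKNEE_MAE_PAIR: tuple[float, float] = (0.187, 0.142)
REFERENCE_EFFICIENCY_50PCT_PAIR: tuple[float, float] = (0.054, 0.030)


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------


def _validate_pair(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0:
        raise InvalidArgumentError("metric requires at least one sample")
    if y.size != y_hat.size:
        raise InvalidArgumentError(f"length mismatch: {y.size} vs {y_hat.size}")
    return y, y_hat


def mse(y, y_hat) -> float:
    """Mean squared error, (N·m/kg)² for moment traces."""
    y, y_hat = _validate_pair(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def mae(y, y_hat) -> float:
    """Mean absolute error, N·m/kg for moment traces."""
    y, y_hat = _validate_pair(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def percent_improvement(baseline: float, improved: float, decimals: int | None = 1) -> float:
    """100·(baseline − improved)/baseline, rounded to one decimal by default."""
    if baseline <= 0:
        raise InvalidArgumentError("baseline must be positive")
    if improved < 0:
        raise InvalidArgumentError("improved value must be nonnegative")
    pct = 100.0 * (baseline - improved) / baseline
    return pct if decimals is None else round(pct, decimals)


def improvement_summary(pairs: list[tuple[float, float]]) -> tuple[float, float, float]:
    """(min %, max %, mean %) of element-wise improvements, at two decimals."""
    if not pairs:
        raise InvalidArgumentError("improvement_summary requires at least one pair")
    pcts = [percent_improvement(b, i, decimals=None) for b, i in pairs]
    return (round(min(pcts), 2), round(max(pcts), 2), round(float(np.mean(pcts)), 2))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-joint errors plus per-time-step curves and multi-seed retention."""

    mse: dict[str, float]
    mae: dict[str, float]
    n_samples: int
    per_timestep: dict[str, np.ndarray] = field(default_factory=dict)
    peaks: pd.DataFrame | None = None
    seeds: list[int] = field(default_factory=list)
    per_seed_mse: dict[str, list[float]] = field(default_factory=dict)


def compute_report(
    observed: np.ndarray, predicted: np.ndarray, channel_names, seed: int | None = None
) -> MetricsReport:
    """Per-joint MSE/MAE and mean-absolute-error-per-time-step curves for
    aligned (N, W, C) moment arrays."""
    if observed.shape != predicted.shape:
        raise InvalidArgumentError(f"shape mismatch: {observed.shape} vs {predicted.shape}")
    names = list(channel_names)
    rep = MetricsReport(mse={}, mae={}, n_samples=observed.shape[0], seeds=[] if seed is None else [seed])
    for c, name in enumerate(names):
        rep.mse[name] = mse(observed[..., c], predicted[..., c])
        rep.mae[name] = mae(observed[..., c], predicted[..., c])
        rep.per_timestep[name] = np.mean(np.abs(observed[..., c] - predicted[..., c]), axis=0)
        rep.per_seed_mse[name] = [rep.mse[name]]
    return rep


def aggregate_runs(per_seed_reports: list[MetricsReport]) -> MetricsReport:
    """Element-wise mean over runs, retaining per-seed MSE values."""
    if not per_seed_reports:
        raise InvalidArgumentError("aggregate_runs requires at least one report")
    first = per_seed_reports[0]
    for rep in per_seed_reports[1:]:
        if set(rep.mse) != set(first.mse) or rep.n_samples != first.n_samples:
            raise SchemaError("reports have heterogeneous structure")
    out = MetricsReport(mse={}, mae={}, n_samples=first.n_samples)
    for name in first.mse:
        out.mse[name] = float(np.mean([r.mse[name] for r in per_seed_reports]))
        out.mae[name] = float(np.mean([r.mae[name] for r in per_seed_reports]))
        curves = [r.per_timestep[name] for r in per_seed_reports if name in r.per_timestep]
        if curves:
            out.per_timestep[name] = np.mean(curves, axis=0)
        out.per_seed_mse[name] = [v for r in per_seed_reports for v in r.per_seed_mse.get(name, [])]
    out.seeds = [s for r in per_seed_reports for s in r.seeds]
    return out


# ---------------------------------------------------------------------------
# Peak / valley analysis
# ---------------------------------------------------------------------------


def peak_valley_report(
    observed: np.ndarray, predicted: np.ndarray, half_window_pct: float = 5.0
) -> pd.DataFrame:
    """Errors at the extrema of the observed cycle-mean moment curve.

    Extrema are strict local maxima/minima of the OBSERVED curve within a
    ±half_window_pct neighbourhood of the normalized cycle. Columns:
    location_pct, kind, observed, predicted, abs_error, rel_error_pct
    (100·|pred − obs| / |obs|).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise InvalidArgumentError("curves must be 1-D and on the same grid")
    n = observed.size
    half = max(1, int(round(half_window_pct / 100.0 * n)))
    rows = []
    # boundary samples with a truncated neighbourhood are not candidate
    # extrema (avoids spurious endpoint peaks on non-wrapped curves)
    for i in range(half, n - half):
        lo, hi = i - half, i + half + 1
        neigh = np.concatenate([observed[lo:i], observed[i + 1 : hi]])
        if np.all(observed[i] > neigh):
            kind = "peak"
        elif np.all(observed[i] < neigh):
            kind = "valley"
        else:
            continue
        abs_err = abs(predicted[i] - observed[i])
        rel = 100.0 * abs_err / abs(observed[i]) if observed[i] != 0 else np.nan
        rows.append(
            {
                "location_pct": 100.0 * i / n,
                "kind": kind,
                "observed": observed[i],
                "predicted": predicted[i],
                "abs_error": abs_err,
                "rel_error_pct": rel,
            }
        )
    if not rows:
        warnings.warn("observed curve has no strict local extrema; empty peak/valley table")
        return pd.DataFrame(
            columns=["location_pct", "kind", "observed", "predicted", "abs_error", "rel_error_pct"]
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Data-efficiency curves
# ---------------------------------------------------------------------------


@dataclass
class EfficiencyCurve:
    """Mean test MSE per label fraction for both arms, plus per-seed values.

    `ssl` and `baseline` are (n_fractions,) means; `ssl_per_seed` /
    `baseline_per_seed` are (n_fractions, n_seeds). Both arms are always
    evaluated on the identical fixed test set.
    """

    fractions: list[float]
    ssl: np.ndarray
    baseline: np.ndarray
    ssl_per_seed: np.ndarray
    baseline_per_seed: np.ndarray
    seeds: list[int]

    def __post_init__(self):
        if list(self.fractions) != sorted(self.fractions):
            raise InvalidArgumentError("fractions must be sorted ascending")
        for arm, name in ((self.ssl_per_seed, "ssl"), (self.baseline_per_seed, "baseline")):
            if arm.shape != (len(self.fractions), len(self.seeds)) or not np.all(np.isfinite(arm)):
                raise IncompleteResultError(f"missing or non-finite {name} arm results")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for fi, f in enumerate(self.fractions):
            for si, s in enumerate(self.seeds):
                rows.append({"fraction": f, "seed": s, "arm": "ssl", "test_mse": self.ssl_per_seed[fi, si]})
                rows.append(
                    {"fraction": f, "seed": s, "arm": "baseline", "test_mse": self.baseline_per_seed[fi, si]}
                )
        return pd.DataFrame(rows)


def efficiency_curve(
    pretrained: TransformerAutoencoder,
    splits: dict[str, WindowSet],
    fractions: list[float],
    seeds: list[int],
    finetune_spec: FinetuneSpec,
    baseline_spec: PretrainSpec,
) -> EfficiencyCurve:
    """Train both arms at every (fraction, seed) and measure fixed-test MSE.

    `splits` carries the joint-selected train/val/test windows (2 input
    angle channels, 2 moment targets). The SSL arm fine-tunes from the
    shared pre-trained encoder; the baseline trains from scratch with the
    pre-training optimizer settings. The test partition is identical for
    every cell.
    """
    fractions = sorted(fractions)
    ssl = np.full((len(fractions), len(seeds)), np.nan)
    base = np.full_like(ssl, np.nan)
    for fi, frac in enumerate(fractions):
        for si, seed in enumerate(seeds):
            ft_spec = replace(finetune_spec, label_fraction=frac, seed=seed)
            m_ssl, _ = finetune(pretrained, splits["train"], splits["val"], ft_spec)
            ssl[fi, si] = _eval_supervised(m_ssl, splits["test"])
            m_base, _ = train_baseline(
                splits["train"], splits["val"], pretrained.spec, baseline_spec, label_fraction=frac, seed=seed
            )
            base[fi, si] = _eval_supervised(m_base, splits["test"])
    return EfficiencyCurve(
        fractions=list(fractions),
        ssl=ssl.mean(axis=1),
        baseline=base.mean(axis=1),
        ssl_per_seed=ssl,
        baseline_per_seed=base,
        seeds=list(seeds),
    )


# ---------------------------------------------------------------------------
# Cross-joint matrix
# ---------------------------------------------------------------------------


@dataclass
class CrossJointMatrix:
    """6×6 test-MSE array: rows = input joint-angle channel, columns =
    target joint-moment channel, both in the fixed order
    (LKnee, RKnee, LAnkle, RAnkle, LHip, RHip)."""

    values: np.ndarray
    joints: tuple[str, ...] = JOINT_ORDER

    def __post_init__(self):
        if self.values.shape != (6, 6):
            raise SchemaError("cross-joint matrix must be 6x6")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise IncompleteResultError("matrix entries must be finite and nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.joints), columns=list(self.joints))

    def diagonal_row_minima(self) -> int:
        """Number of (row, off-diagonal column) comparisons the diagonal wins:
        diag ≤ off-diag entry, out of 30 such comparisons (plus the 6 trivial
        diagonal self-comparisons, giving the conventional /36 count)."""
        wins = 6  # each diagonal trivially ties itself
        for j in range(6):
            for k in range(6):
                if j != k and self.values[j, j] <= self.values[j, k]:
                    wins += 1
        return wins


def cross_joint_matrix(
    pretrained: TransformerAutoencoder,
    splits: dict[str, WindowSet],
    finetune_spec: FinetuneSpec,
    seed: int = 0,
) -> CrossJointMatrix:
    """Fine-tune one single-channel regression head per (input angle, target
    moment) pair from the shared pre-trained encoder and record test MSE."""
    values = np.full((6, 6), np.nan)
    for j, angle in enumerate(SAGITTAL_ANGLES):
        tr = splits["train"].select_channels([angle], list(MOMENT_CHANNELS))
        va = splits["val"].select_channels([angle], list(MOMENT_CHANNELS))
        te = splits["test"].select_channels([angle], list(MOMENT_CHANNELS))
        for k, moment in enumerate(MOMENT_CHANNELS):
            ft_spec = replace(finetune_spec, seed=seed)
            m, _ = finetune(
                pretrained,
                dataclasses.replace(
                    tr, targets=tr.targets[:, :, [k]], target_names=(moment,)
                ),
                dataclasses.replace(va, targets=va.targets[:, :, [k]], target_names=(moment,)),
                ft_spec,
            )
            te_k = dataclasses.replace(te, targets=te.targets[:, :, [k]], target_names=(moment,))
            values[j, k] = _eval_supervised(m, te_k)
    return CrossJointMatrix(values=values)
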