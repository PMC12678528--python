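"""Linear lead transforms: y = A x + C per time sample.

The transform maps input channels (raw leads, optionally augmented with masked
wave channels) to the five reconstructed precordial leads.  ``fit_ols`` is the
closed-form least-squares solution (minimum-norm under rank deficiency) and
serves as the correctness anchor for ``fit_sgd``, the mini-batch stochastic
gradient fit used for large datasets.  The four limb leads are derived
algebraically from leads I and II (Einthoven / Goldberger identities), so only
the precordials are regression targets.

Every time sample of every training record is one observation; training folds
pool samples across patients (one generic transform per fold, not per-patient
models).  SGD runs on channels standardized with training statistics; the
stored model always predicts in raw millivolts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .delineate import FiducialSet, delineate
from .io import ECGRecord
from .masking import CHANNEL_NAMES, DEFAULT_WAVE_LEADS, build_augmented_input

__all__ = [
    "LinearLeadModel",
    "SGDConfig",
    "PipelineConfig",
    "VARIANTS",
    "fit_ols",
    "fit_sgd",
    "predict",
    "derive_limb_leads",
    "make_pipeline",
    "LinearReconstructionPipeline",
    "save_model",
    "load_model",
]


@dataclass
class ScalingState:
    """Training-fold channel statistics used to standardize internally."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray

    @classmethod
    def identity(cls, n_in: int, n_out: int) -> "ScalingState":
        return cls(np.zeros(n_in), np.ones(n_in), np.zeros(n_out), np.ones(n_out))

    @classmethod
    def from_data(cls, X: np.ndarray, Y: np.ndarray) -> "ScalingState":
        x_scale = X.std(axis=0)
        y_scale = Y.std(axis=0)
        # constant channels get unit scale so standardization stays invertible
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
        y_scale = np.where(y_scale > 0, y_scale, 1.0)
        return cls(X.mean(axis=0), x_scale, Y.mean(axis=0), y_scale)


@dataclass
class LinearLeadModel:
    """Coefficients A (n_outputs x n_inputs) and intercept C, in raw mV."""

    A: np.ndarray
    C: np.ndarray
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    scaling: ScalingState | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.input_names = tuple(self.input_names)
        self.output_names = tuple(self.output_names)
        if self.A.shape != (len(self.output_names), len(self.input_names)):
            raise ValueError(
                f"A shape {self.A.shape} does not match "
                f"{len(self.output_names)} outputs x {len(self.input_names)} inputs"
            )
        if self.C.shape != (len(self.output_names),):
            raise ValueError(f"C shape {self.C.shape} does not match outputs")


def _check_xy(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D (observations x channels)")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} observations but Y has {Y.shape[0]}")
    return X, Y


def _names(names, m, prefix):
    if names is None:
        return tuple(f"{prefix}{i}" for i in range(m))
    names = tuple(names)
    if len(names) != m:
        raise ValueError(f"{len(names)} {prefix}-names for {m} channels")
    return names


def fit_ols(
    X: np.ndarray,
    Y: np.ndarray,
    input_names: Sequence[str] | None = None,
    output_names: Sequence[str] | None = None,
) -> LinearLeadModel:
    """Closed-form least squares for y = A x + C.

    Centering removes the intercept from the normal equations;
    ``numpy.linalg.lstsq`` returns the minimum-norm coefficient matrix when the
    input channels are rank-deficient (a warning is emitted).
    """
    X, Y = _check_xy(X, Y)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations for {k} inputs, got {n}")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    coef, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
    if rank < k:
        warnings.warn(
            f"rank-deficient inputs (rank {rank} < {k}); minimum-norm solution returned",
            stacklevel=2,
        )
    A = coef.T
    C = y_mean - A @ x_mean
    return LinearLeadModel(
        A=A,
        C=C,
        input_names=_names(input_names, k, "x"),
        output_names=_names(output_names, Y.shape[1], "y"),
        meta={"method": "ols", "rank": int(rank)},
    )


@dataclass(frozen=True)
class SGDConfig:
    """Mini-batch SGD hyperparameters (standardized-channel updates)."""

    learning_rate: float = 5e-2
    epochs: int = 50
    batch_size: int = 1024
    momentum: float = 0.9
    seed: int = 0
    tol: float = 1e-9


def fit_sgd(
    X: np.ndarray,
    Y: np.ndarray,
    hyper: SGDConfig = SGDConfig(),
    input_names: Sequence[str] | None = None,
    output_names: Sequence[str] | None = None,
) -> LinearLeadModel:
    """Mini-batch SGD fit of the linear transform, deterministic given its seed.

    Channels are standardized with the training statistics; the stored A and C
    are mapped back to raw millivolts, so predictions are independent of the
    internal scaling.  Raises on divergence (non-finite loss).
    """
    X, Y = _check_xy(X, Y)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations for {k} inputs, got {n}")
    scaling = ScalingState.from_data(X, Y)
    Xs = (X - scaling.x_mean) / scaling.x_scale
    Ys = (Y - scaling.y_mean) / scaling.y_scale
    rng = np.random.default_rng(hyper.seed)
    m = Ys.shape[1]
    W = np.zeros((k, m))
    b = np.zeros(m)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    prev_loss = np.inf
    losses: list[float] = []
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            Xb, Yb = Xs[idx], Ys[idx]
            resid = Xb @ W + b - Yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"SGD diverged (non-finite loss) at epoch {epoch}; lower the learning rate"
                )
            gW = 2.0 * Xb.T @ resid / len(idx)
            gb = 2.0 * resid.mean(axis=0)
            vW = hyper.momentum * vW - hyper.learning_rate * gW
            vb = hyper.momentum * vb - hyper.learning_rate * gb
            W += vW
            b += vb
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        losses.append(epoch_loss)
        if abs(prev_loss - epoch_loss) < hyper.tol:
            break
        prev_loss = epoch_loss
    # map standardized coefficients back to raw mV
    A = (scaling.y_scale[:, None] * W.T) / scaling.x_scale[None, :]
    C = scaling.y_mean + scaling.y_scale * b - A @ scaling.x_mean
    return LinearLeadModel(
        A=A,
        C=C,
        input_names=_names(input_names, k, "x"),
        output_names=_names(output_names, m, "y"),
        scaling=scaling,
        meta={
            "method": "sgd",
            "hyper": asdict(hyper),
            "loss_curve": losses,
            "W_std": W.T.tolist(),
            "b_std": b.tolist(),
        },
    )


def predict(
    model: LinearLeadModel,
    X: np.ndarray,
    input_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Apply y = A x + C per sample; refuses silently reordered channels."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.input_names):
        raise ValueError(
            f"X has shape {X.shape}; model expects {len(model.input_names)} input channels"
        )
    if input_names is not None and tuple(input_names) != model.input_names:
        raise ValueError(
            f"input channel names {tuple(input_names)} do not match model "
            f"{model.input_names} (no silent reordering)"
        )
    return X @ model.A.T + model.C


def standardized_coefficients(model: LinearLeadModel) -> np.ndarray:
    """A expressed on unit-variance channels (for SGD-vs-OLS comparisons)."""
    if model.scaling is None:
        raise ValueError("model carries no scaling state")
    s = model.scaling
    return model.A * s.x_scale[None, :] / s.y_scale[:, None]


def derive_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray) -> dict[str, np.ndarray]:
    """Einthoven / Goldberger identities: III, aVR, aVL, aVF from I and II."""
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    if lead_i.shape != lead_ii.shape:
        raise ValueError(f"lead shapes differ: {lead_i.shape} vs {lead_ii.shape}")
    return {
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

#: variant -> (input channel names, output lead names)
VARIANTS: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "p1": (("I", "II", "V2"), ("V1", "V3", "V4", "V5", "V6")),
    "p2": (("I", "II", "V3"), ("V1", "V2", "V4", "V5", "V6")),
    "wmlr": (CHANNEL_NAMES, ("V1", "V2", "V4", "V5", "V6")),
    "lstm": (("I", "II", "V3"), ("V1", "V2", "V4", "V5", "V6")),
    "ffn": (("I", "II", "V3"), ("V1", "V2", "V4", "V5", "V6")),
}


@dataclass
class PipelineConfig:
    """Which reconstruction variant to run and how to fit it.

    ``fiducials`` selects where the wave-masked variant gets its segment
    boundaries: ``"provided"`` uses the FiducialSet attached to each dataset
    item (e.g. generator truth or imported annotations), ``"internal"`` runs
    the package delineator on leads I, II, V3.
    """

    variant: str = "p2"
    fit_method: str = "ols"  # ols | sgd
    sgd: SGDConfig = field(default_factory=SGDConfig)
    wave_leads: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_WAVE_LEADS))
    fiducials: str = "provided"  # provided | internal
    dl: "object | None" = None  # DLConfig for lstm/ffn variants

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}")
        if self.fit_method not in {"ols", "sgd"}:
            raise ValueError(f"unknown fit_method {self.fit_method!r}")
        if self.fiducials not in {"provided", "internal"}:
            raise ValueError(f"unknown fiducials mode {self.fiducials!r}")


class LinearReconstructionPipeline:
    """Train/predict wrapper around one linear variant (p1, p2 or wmlr)."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.input_names, self.output_names = VARIANTS[config.variant]
        self.model: LinearLeadModel | None = None

    def clone(self) -> "LinearReconstructionPipeline":
        return make_pipeline(self.config)

    # -- data assembly ------------------------------------------------------

    def _fiducials_for(self, item) -> FiducialSet:
        if self.config.fiducials == "internal":
            return delineate(item.record)
        fid = getattr(item, "fiducials", None)
        if fid is None:
            raise ValueError(
                f"record {item.record.record_id!r} carries no fiducials; "
                "use fiducials='internal' or attach a FiducialSet"
            )
        return fid

    def build_input(self, item) -> np.ndarray:
        record: ECGRecord = item.record
        if self.config.variant == "wmlr":
            aug = build_augmented_input(
                record, self._fiducials_for(item), self.config.wave_leads
            )
            return aug.to_matrix()
        return record.subset(self.input_names)

    def build_target(self, item) -> np.ndarray:
        return item.record.subset(self.output_names)

    # -- fitting / prediction ----------------------------------------------

    def fit(self, items: Sequence) -> "LinearReconstructionPipeline":
        if not items:
            raise ValueError("empty training set")
        X = np.vstack([self.build_input(it) for it in items])
        Y = np.vstack([self.build_target(it) for it in items])
        if self.config.fit_method == "sgd":
            self.model = fit_sgd(X, Y, self.config.sgd, self.input_names, self.output_names)
        else:
            self.model = fit_ols(X, Y, self.input_names, self.output_names)
        return self

    def predict(self, item) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        return predict(self.model, self.build_input(item))


def make_pipeline(config: PipelineConfig):
    """Build the train/predict object for a variant (linear or DL baseline)."""
    if config.variant in {"p1", "p2", "wmlr"}:
        return LinearReconstructionPipeline(config)
    from .baselines import DLPipeline  # lazy: keeps linear path dependency-light

    return DLPipeline(config)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: LinearLeadModel, path: str | Path) -> None:
    payload = {
        "A": model.A.tolist(),
        "C": model.C.tolist(),
        "input_names": list(model.input_names),
        "output_names": list(model.output_names),
        "scaling": None
        if model.scaling is None
        else {
            "x_mean": model.scaling.x_mean.tolist(),
            "x_scale": model.scaling.x_scale.tolist(),
            "y_mean": model.scaling.y_mean.tolist(),
            "y_scale": model.scaling.y_scale.tolist(),
        },
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> LinearLeadModel:
    payload = json.loads(Path(path).read_text())
    scaling = payload.get("scaling")
    return LinearLeadModel(
        A=np.asarray(payload["A"], dtype=float),
        C=np.asarray(payload["C"], dtype=float),
        input_names=tuple(payload["input_names"]),
        output_names=tuple(payload["output_names"]),
        scaling=None
        if scaling is None
        else ScalingState(
            np.asarray(scaling["x_mean"]),
            np.asarray(scaling["x_scale"]),
            np.asarray(scaling["y_mean"]),
            np.asarray(scaling["y_scale"]),
        ),
        meta=payload.get("meta", {}),
    )
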