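"""Thermostability regression and activity-discriminant heads.

The architecture mirrors the fine-tuning setup used with protein language
models for stability prediction: the per-residue representation is mean-pooled
to one vector per variant, which feeds a small MLP head (one hidden layer,
Tanh activation, dropout) producing a single score.  Training uses the Adam
optimizer with MSE loss for the regression head (melting temperature, degC) and
binary cross-entropy for the discriminant head (relative activity above an
acceptability threshold, default "more than 60% of wild type").

Organisation follows the statsmodels convention: build a
:class:`StabilityModel` from data, call :meth:`~StabilityModel.fit`, and work
with the returned :class:`StabilityResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .encoders import EmbeddingEncoder, EncoderBackend, OneHotEncoder, get_backend
from .variants import Mutation, Variant, WILD_TYPE, parse_variant


class TrainingError(RuntimeError):
    pass


@dataclass
class VariantRecord:
    """One labeled variant: the training datum of the campaign.

    At least one of ``tm`` (melting temperature, degC) or ``relative_activity``
    (% of wild type) must be present.  ``round`` indexes the design round the
    measurement came from (0 = initial data set).
    """

    variant: Variant
    tm: float | None = None
    relative_activity: float | None = None
    round: int = 0

    def __post_init__(self) -> None:
        if self.tm is None and self.relative_activity is None:
            raise ValueError(f"record {self.variant} carries no label")
        if self.relative_activity is not None and self.relative_activity < 0:
            raise ValueError("relative_activity must be >= 0")
        if self.round < 0:
            raise ValueError("round must be >= 0")


@dataclass
class HeadConfig:
    """Hyperparameters of one prediction head.

    Defaults follow the published fine-tuning recipe: Adam, learning rate
    1e-5, batch size 4, at most 200 epochs, early stop after 10 epochs without
    improvement.  The learning rate is appropriate for pretrained-PLM-scale
    features; surrogate one-hot features typically need a larger value
    (see docs/methods.md).
    """

    hidden: tuple[int, ...] = (128,)
    dropout: float = 0.1
    learning_rate: float = 1e-5
    batch_size: int = 4
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    task: str = "regression"  # or "discriminant"
    val_fraction: float = 0.1
    min_val_records: int = 20
    activity_threshold: float = 60.0
    finetune_encoder: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.task not in ("regression", "discriminant"):
            raise ValueError(f"unknown task {self.task!r}")


# ---------------------------------------------------------------------------
# small MLP with hand-rolled Adam (the head is tiny; no autodiff needed)
# ---------------------------------------------------------------------------


def _init_params(widths: Sequence[int], rng: np.random.Generator,
                 first_has_bias: bool = True) -> list[dict]:
    params = []
    for i, (n_in, n_out) in enumerate(zip(widths[:-1], widths[1:])):
        scale = np.sqrt(1.0 / n_in)
        layer = {"W": rng.normal(0.0, scale, size=(n_in, n_out))}
        layer["b"] = np.zeros(n_out) if (first_has_bias or i > 0) else None
        params.append(layer)
    return params


def _forward(params, X, *, dropout=0.0, rng=None):
    """Return (output (n,), cache for backprop).  Hidden layers: tanh + dropout."""
    a = X
    cache = []
    n_layers = len(params)
    for i, layer in enumerate(params):
        z = a @ layer["W"]
        if layer["b"] is not None:
            z = z + layer["b"]
        if i < n_layers - 1:
            h = np.tanh(z)
            mask = None
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
            cache.append((a, h if mask is None else None, mask, np.tanh(z)))
            a = h
        else:
            cache.append((a, None, None, None))
            a = z
    return a[:, 0], cache


def _backward(params, cache, dout):
    """Gradient of the loss wrt each parameter, given d(loss)/d(output)."""
    grads = [dict() for _ in params]
    da = dout[:, None]
    for i in range(len(params) - 1, -1, -1):
        a_in, _, mask, tanh_z = cache[i]
        dz = da
        if i < len(params) - 1:
            if mask is not None:
                dz = dz * mask
            dz = dz * (1.0 - tanh_z**2)
        grads[i]["W"] = a_in.T @ dz
        grads[i]["b"] = dz.sum(axis=0) if params[i]["b"] is not None else None
        da = dz @ params[i]["W"].T
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items() if v is not None}
                  for p in params]
        self.v = [{k: np.zeros_like(v) for k, v in p.items() if v is not None}
                  for p in params]

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            for k in m:
                if g[k] is None:
                    continue
                m[k] = self.b1 * m[k] + (1 - self.b1) * g[k]
                v[k] = self.b2 * v[k] + (1 - self.b2) * g[k] ** 2
                mhat = m[k] / (1 - self.b1**self.t)
                vhat = v[k] / (1 - self.b2**self.t)
                p[k] = p[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class StabilityModel:
    """Prediction head over a pooled sequence representation.

    Parameters
    ----------
    records : list of VariantRecord
        Labeled variants; records lacking the label required by
        ``config.task`` are dropped with a count reported at fit time.
    wild_type : str
        The parent protein sequence; all variants validate against it.
    backend : EncoderBackend, optional
        Representation backend (default: one-hot).
    config : HeadConfig, optional
    """

    MIN_RECORDS = 8

    def __init__(self, records: Sequence[VariantRecord], wild_type: str,
                 backend: EncoderBackend | None = None,
                 config: HeadConfig | None = None):
        self.records = list(records)
        self.wild_type = wild_type
        self.backend = backend if backend is not None else OneHotEncoder()
        self.config = config if config is not None else HeadConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, wild_type: str, **kwargs) -> "StabilityModel":
        """Build from the labeled-data table
        (columns ``variant, tm_celsius, relative_activity_percent, round``)."""
        records = records_from_dataframe(df, wild_type)
        return cls(records, wild_type, **kwargs)

    # -- label extraction ---------------------------------------------------

    def _training_arrays(self):
        cfg = self.config
        usable, y = [], []
        for r in self.records:
            if cfg.task == "regression":
                if r.tm is None:
                    continue
                y.append(r.tm)
            else:
                if r.relative_activity is None:
                    continue
                y.append(1.0 if r.relative_activity > cfg.activity_threshold else 0.0)
            usable.append(r.variant)
        if len(usable) < self.MIN_RECORDS:
            raise TrainingError(
                f"{len(usable)} records carry a {cfg.task} label; "
                f"need at least {self.MIN_RECORDS}"
            )
        return usable, np.asarray(y, dtype=float)

    def _features(self, variants) -> np.ndarray:
        if self.config.finetune_encoder and isinstance(self.backend, EmbeddingEncoder):
            from .variants import apply_variant
            return np.stack([
                EmbeddingEncoder.composition(apply_variant(v, self.wild_type))
                for v in variants
            ])
        return self.backend.feature_matrix(variants, self.wild_type)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "StabilityResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        variants, y_raw = self._training_arrays()
        X = self._features(variants)

        if cfg.task == "regression":
            y_mean = float(y_raw.mean())
            y_std = float(y_raw.std())
            if y_std == 0.0:
                y_std = 1.0
            y = (y_raw - y_mean) / y_std
        else:
            y_mean, y_std = 0.0, 1.0
            y = y_raw

        n = len(y)
        if n >= cfg.min_val_records and cfg.val_fraction > 0:
            n_val = max(1, int(round(cfg.val_fraction * n)))
            perm = rng.permutation(n)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        else:
            train_idx = np.arange(n)
            val_idx = None

        Xtr, ytr = X[train_idx], y[train_idx]
        finetune = cfg.finetune_encoder and isinstance(self.backend, EmbeddingEncoder)
        if finetune:
            widths = [X.shape[1], self.backend.dim, *cfg.hidden, 1]
            params = _init_params(widths, rng, first_has_bias=False)
            params[0]["W"] = self.backend.table.copy()
        else:
            widths = [X.shape[1], *cfg.hidden, 1]
            params = _init_params(widths, rng)

        adam = _Adam(params, cfg.learning_rate)
        history: list[dict] = []
        best = np.inf
        best_params = None
        best_epoch = -1

        def full_loss(idx):
            pred, _ = _forward(params, X[idx])
            if cfg.task == "regression":
                return float(np.mean((pred - y[idx]) ** 2))
            p = _sigmoid(pred)
            eps = 1e-12
            return float(-np.mean(y[idx] * np.log(p + eps)
                                  + (1 - y[idx]) * np.log(1 - p + eps)))

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(ytr))
            for start in range(0, len(ytr), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                out, cache = _forward(params, xb, dropout=cfg.dropout, rng=rng)
                if cfg.task == "regression":
                    dout = 2.0 * (out - yb) / len(yb)
                else:
                    dout = (_sigmoid(out) - yb) / len(yb)
                grads = _backward(params, cache, dout)
                adam.step(params, grads)

            train_loss = full_loss(train_idx)
            val_loss = full_loss(val_idx) if val_idx is not None else None
            monitored = val_loss if val_loss is not None else train_loss
            if not np.isfinite(monitored):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} "
                    f"(train={train_loss}, val={val_loss}); "
                    "check learning rate and label scale"
                )
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss, "monitored": monitored})
            if monitored < best:
                best = monitored
                best_epoch = epoch
                best_params = [{k: (v.copy() if v is not None else None)
                                for k, v in p.items()} for p in params]
            elif epoch - best_epoch >= cfg.patience:
                break

        return StabilityResults(
            model=self,
            params=best_params,
            history=history,
            y_mean=y_mean,
            y_std=y_std,
            n_train=len(train_idx),
            n_val=0 if val_idx is None else len(val_idx),
            best_epoch=best_epoch,
            best_loss=best,
        )


class StabilityResults:
    """Fitted head: predictions, training history, persistence, summary."""

    def __init__(self, model, params, history, y_mean, y_std,
                 n_train, n_val, best_epoch, best_loss):
        self.model = model
        self.params = params
        self.history = history
        self.y_mean = y_mean
        self.y_std = y_std
        self.n_train = n_train
        self.n_val = n_val
        self.best_epoch = best_epoch
        self.best_loss = best_loss

    @property
    def config(self) -> HeadConfig:
        return self.model.config

    # -- prediction (dropout disabled; chunked so 2^n spaces stream) --------

    def _scores(self, variants: Iterable[Variant], chunk: int = 1024):
        buf: list[Variant] = []
        for v in variants:
            buf.append(v)
            if len(buf) == chunk:
                yield buf, self._forward_chunk(buf)
                buf = []
        if buf:
            yield buf, self._forward_chunk(buf)

    def _forward_chunk(self, variants) -> np.ndarray:
        X = self.model._features(variants)
        out, _ = _forward(self.params, X)
        return out

    def predict_tm_score(self, variants: Iterable[Variant]) -> list[tuple[Variant, float]]:
        """Predicted melting temperature (degC, de-normalized) per variant."""
        if self.config.task != "regression":
            raise TrainingError("this head was trained as a discriminant, not regression")
        results = []
        for batch, out in self._scores(variants):
            tm = out * self.y_std + self.y_mean
            results.extend(zip(batch, tm.tolist()))
        return results

    def predict_activity_acceptable(
        self, variants: Iterable[Variant], threshold: float = 0.5,
    ) -> list[tuple[Variant, bool, float]]:
        """(variant, acceptable, probability) per variant.

        ``threshold`` is the probability cut (default 0.5); the activity-%
        cut that defined the training classes lives in the config.
        """
        if self.config.task != "discriminant":
            raise TrainingError("this head was trained for regression, not discriminant")
        results = []
        for batch, out in self._scores(variants):
            p = _sigmoid(out)
            results.extend(
                (v, bool(pi >= threshold), float(pi)) for v, pi in zip(batch, p)
            )
        return results

    def single_mutation_effects(self, candidates: Sequence[Mutation]) -> dict[Mutation, float]:
        """Predicted effect of each candidate single relative to predicted WT."""
        variants = [WILD_TYPE] + [Variant([m]) for m in candidates]
        preds = dict(self.predict_tm_score(variants))
        wt = preds[WILD_TYPE]
        return {m: preds[Variant([m])] - wt for m in candidates}

    # -- bookkeeping ---------------------------------------------------------

    def normalize(self, y):
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def denormalize(self, z):
        return np.asarray(z, dtype=float) * self.y_std + self.y_mean

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Stability head fit",
            "==================",
            f"task:             {cfg.task}",
            f"backend:          {self.model.backend.name} (D={self.model.backend.dim})",
            f"hidden widths:    {cfg.hidden}  dropout: {cfg.dropout}",
            f"records (train/val): {self.n_train}/{self.n_val}",
            f"epochs run:       {len(self.history)} (best at {self.best_epoch})",
            f"best monitored loss: {self.best_loss:.6g}",
        ]
        if cfg.task == "regression":
            lines.append(f"label scale:      mean={self.y_mean:.3f} degC, sd={self.y_std:.3f} degC")
        else:
            lines.append(f"activity class:   > {cfg.activity_threshold}% of WT")
        return "\n".join(lines)

    # -- persistence (portable JSON checkpoint) ------------------------------

    def save(self, path) -> None:
        blob = {
            "format": "thermocomb-head-v1",
            "config": asdict(self.config),
            "backend": self.model.backend.name,
            "backend_dim": self.model.backend.dim,
            "wild_type": self.model.wild_type,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "best_epoch": self.best_epoch,
            "best_loss": self.best_loss,
            "history": self.history,
            "params": [
                {k: (v.tolist() if v is not None else None) for k, v in p.items()}
                for p in self.params
            ],
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path, backend: EncoderBackend | None = None) -> "StabilityResults":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "thermocomb-head-v1":
            raise TrainingError(f"{path} is not a thermocomb head checkpoint")
        cfg_dict = dict(blob["config"])
        cfg_dict["hidden"] = tuple(cfg_dict["hidden"])
        cfg = HeadConfig(**cfg_dict)
        if backend is None:
            if blob["backend"] == "embedding":
                backend = get_backend("embedding", dim=blob["backend_dim"])
            elif blob["backend"] == "precomputed":
                raise TrainingError("pass the PrecomputedEncoder explicitly when loading")
            else:
                backend = get_backend(blob["backend"])
        model = StabilityModel([], blob["wild_type"], backend=backend, config=cfg)
        params = [
            {k: (np.asarray(v) if v is not None else None) for k, v in p.items()}
            for p in blob["params"]
        ]
        return cls(model=model, params=params, history=blob["history"],
                   y_mean=blob["y_mean"], y_std=blob["y_std"],
                   n_train=blob["n_train"], n_val=blob["n_val"],
                   best_epoch=blob["best_epoch"], best_loss=blob["best_loss"])


# ---------------------------------------------------------------------------
# labeled-table IO
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["variant", "tm_celsius", "relative_activity_percent", "round"]


def records_from_dataframe(df: pd.DataFrame, wild_type: str | None = None) -> list[VariantRecord]:
    records = []
    for _, row in df.iterrows():
        tm = row.get("tm_celsius")
        act = row.get("relative_activity_percent")
        records.append(VariantRecord(
            variant=parse_variant(str(row["variant"]), wild_type),
            tm=None if pd.isna(tm) else float(tm),
            relative_activity=None if pd.isna(act) else float(act),
            round=int(row.get("round", 0) or 0),
        ))
    return records


def records_to_dataframe(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "variant": [str(r.variant) for r in records],
        "tm_celsius": [r.tm for r in records],
        "relative_activity_percent": [r.relative_activity for r in records],
        "round": [r.round for r in records],
    })
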