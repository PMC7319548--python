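"""The compression core: per-residue autoencoders with a 1-D bottleneck.

Each residue's standardized shift vector is pushed through an encoder
(input -> tanh hidden -> single logistic neuron) and a mirrored decoder
(bottleneck -> tanh hidden -> linear output), trained to reconstruct the
input.  The logistic bottleneck value in (0, 1) is the per-residue
compressed shift value: because the dominant axis of variation in
chemical-shift space is secondary structure, a 1-D bottleneck that
minimizes reconstruction error orders residues along the helix-coil-sheet
continuum.

Because the input dimension differs between residue types (glycine lacks
CB, proline the amide proton), one encoder/decoder pair is fitted per
residue type.  Cross-type comparability is imposed afterwards by
orientation calibration: the sign of a bottleneck is arbitrary under
training, so each type's output is flipped (v -> 1 - v) if needed to make
helix map low and sheet high, globally.  Coil then sits in between, near
0.5.

The reconstruction loss is masked: squared error is accumulated over
observed entries only and normalized by the observed count, so imputed
zeros for missing atoms are never penalized.  Training is deterministic
given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .encoding import (EncodingScheme, NormStats, AtomStats, ResidueVector,
                       build_scheme, encode_residue, fit_norm_stats)
from .shift_io import ProfileRecord, ShiftTable

logger = logging.getLogger(__name__)

MODEL_FORMAT = "shiftcrypt-model"
MODEL_VERSION = "1"

_PARAM_NAMES = ("W1", "b1", "w2", "b2", "V1", "c1", "V2", "c2")


@dataclass
class Hyperparams:
    """Training configuration.

    hidden_mult — hidden width as a multiple of the input dimension;
    epochs/learning_rate/batch_size — Adam schedule; val_fraction —
    held-out share of proteins (split by protein, never by residue, to
    avoid leaking within-chain correlation); min_residues — below this
    per-type count a warning is emitted (the fit still runs).
    """

    hidden_mult: int = 2
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 256
    val_fraction: float = 0.1
    min_residues: int = 200


@dataclass
class TrainReport:
    """Per-epoch masked reconstruction losses and the mean-predictor baseline."""

    epoch_train_loss: list[float]
    epoch_val_loss: list[float]
    baseline_loss: float                 # masked MSE of predicting 0 (the mean)
    per_type_val_loss: dict[str, float]
    n_train_residues: int
    n_val_residues: int

    @property
    def final_val_loss(self) -> float:
        return self.epoch_val_loss[-1]


@dataclass
class ShiftCryptModel:
    """Fitted compression model: stats + per-type weights + orientation."""

    scheme_name: str
    stats: NormStats
    nets: dict[str, dict[str, np.ndarray]]
    flip: dict[str, bool]
    hyperparams: dict
    version: str = MODEL_VERSION

    def bottleneck(self, vec: ResidueVector) -> Optional[float]:
        """Oriented bottleneck value for an encoded residue, or None."""
        net = self.nets.get(vec.residue_type)
        if net is None or not vec.mask.any():
            return None
        h1 = np.tanh(net["W1"] @ vec.values + net["b1"])
        z = float(_sigmoid(net["w2"] @ h1 + net["b2"][0]))
        if self.flip.get(vec.residue_type, False):
            z = 1.0 - z
        return z

    def reconstruct(self, vec: ResidueVector) -> np.ndarray:
        """Decoder output for an encoded residue (same layout as input)."""
        net = self.nets[vec.residue_type]
        h1 = np.tanh(net["W1"] @ vec.values + net["b1"])
        z = _sigmoid(net["w2"] @ h1 + net["b2"])
        h2 = np.tanh(net["V1"] * z + net["c1"])
        return net["V2"] @ h2 + net["c2"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _init_net(d: int, hidden: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        "W1": rng.normal(0.0, 1.0 / np.sqrt(d), (hidden, d)),
        "b1": np.zeros(hidden),
        "w2": rng.normal(0.0, 1.0 / np.sqrt(hidden), hidden),
        "b2": np.zeros(1),
        "V1": rng.normal(0.0, 1.0, hidden),
        "c1": np.zeros(hidden),
        "V2": rng.normal(0.0, 1.0 / np.sqrt(hidden), (d, hidden)),
        "c2": np.zeros(d),
    }


def _forward(net, X):
    H1 = np.tanh(X @ net["W1"].T + net["b1"])
    Z = _sigmoid(H1 @ net["w2"] + net["b2"][0])
    H2 = np.tanh(np.outer(Z, net["V1"]) + net["c1"])
    Y = H2 @ net["V2"].T + net["c2"]
    return H1, Z, H2, Y


def masked_loss(net: dict[str, np.ndarray], X: np.ndarray, M: np.ndarray) -> float:
    """Masked reconstruction MSE: sum over observed entries / observed count."""
    _, _, _, Y = _forward(net, X)
    return float(np.sum(M * (Y - X) ** 2) / np.sum(M))


def _grads(net, X, M):
    H1, Z, H2, Y = _forward(net, X)
    total = np.sum(M)
    dY = 2.0 * M * (Y - X) / total
    g = {}
    g["V2"] = dY.T @ H2
    g["c2"] = dY.sum(axis=0)
    dH2 = dY @ net["V2"]
    dP2 = dH2 * (1.0 - H2 ** 2)
    g["V1"] = dP2.T @ Z
    g["c1"] = dP2.sum(axis=0)
    dZ = dP2 @ net["V1"]
    dPz = dZ * Z * (1.0 - Z)
    g["w2"] = dPz @ H1
    g["b2"] = np.array([dPz.sum()])
    dH1 = np.outer(dPz, net["w2"])
    dP1 = dH1 * (1.0 - H1 ** 2)
    g["W1"] = dP1.T @ X
    g["b1"] = dP1.sum(axis=0)
    loss = float(np.sum(M * (Y - X) ** 2) / total)
    return g, loss


def _encode_by_type(tables: Sequence[ShiftTable], scheme: EncodingScheme,
                    stats: NormStats) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Observed residue vectors grouped by type -> (X, M) arrays."""
    rows: dict[str, list[ResidueVector]] = {}
    for table in tables:
        for res in table:
            vec = encode_residue(res, scheme, stats)
            if vec.mask.any():
                rows.setdefault(res.residue_type, []).append(vec)
    return {
        rt: (np.array([v.values for v in vecs]), np.array([v.mask for v in vecs]))
        for rt, vecs in rows.items()
    }


def train(tables: Sequence[ShiftTable], scheme_name: str = "reduced",
          hyperparams: Optional[Hyperparams] = None, seed: int = 42,
          min_count: int = 50) -> tuple[ShiftCryptModel, TrainReport]:
    """Fit per-residue-type autoencoders on a corpus of shift tables.

    The corpus is split into train/validation by protein (deterministic in
    ``seed``); normalization statistics come from the training share only.
    Returns the model (orientation uncalibrated: no flips yet) and a
    report with per-epoch masked losses, aggregated over residue types
    weighted by observed-entry count, plus the mean-predictor baseline.
    """
    hp = hyperparams or Hyperparams()
    tables = list(tables)
    if not tables:
        raise ValueError("no training tables given")
    scheme = build_scheme(scheme_name)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tables))
    n_val = int(round(hp.val_fraction * len(tables)))
    if len(tables) > 1:
        n_val = min(max(n_val, 1), len(tables) - 1)
    else:
        n_val = 0
    val_tables = [tables[i] for i in order[:n_val]]
    train_tables = [tables[i] for i in order[n_val:]]

    stats = fit_norm_stats(train_tables, scheme, min_count=min_count)
    train_data = _encode_by_type(train_tables, scheme, stats)
    val_data = _encode_by_type(val_tables, scheme, stats)

    nets: dict[str, dict[str, np.ndarray]] = {}
    types = sorted(train_data)
    curves: dict[str, tuple[list[float], list[float]]] = {}
    for ti, rt in enumerate(types):
        X, M = train_data[rt]
        if X.shape[0] < hp.min_residues:
            logger.warning("residue type %s: only %d training residues "
                           "(recommended >= %d)", rt, X.shape[0], hp.min_residues)
        hidden = hp.hidden_mult * X.shape[1]
        net_rng = np.random.default_rng([seed, ti])
        nets[rt], curves[rt] = _train_net(X, M, val_data.get(rt), hidden,
                                          hp, net_rng)

    epoch_train, epoch_val = _aggregate_curves(curves, train_data, val_data,
                                               hp.epochs)

    per_type_val: dict[str, float] = {}
    for rt, net in nets.items():
        Xv, Mv = val_data.get(rt, train_data[rt])
        per_type_val[rt] = masked_loss(net, Xv, Mv)

    eval_data = val_data if val_data else train_data
    base_num = sum(float(np.sum(M * X ** 2)) for X, M in eval_data.values())
    base_den = sum(float(np.sum(M)) for _, M in eval_data.values())
    baseline = base_num / base_den if base_den else float("nan")

    model = ShiftCryptModel(
        scheme_name=scheme_name, stats=stats, nets=nets,
        flip={rt: False for rt in nets},
        hyperparams={"hidden_mult": hp.hidden_mult, "epochs": hp.epochs,
                     "learning_rate": hp.learning_rate,
                     "batch_size": hp.batch_size,
                     "val_fraction": hp.val_fraction, "seed": seed},
    )
    report = TrainReport(
        epoch_train_loss=epoch_train, epoch_val_loss=epoch_val,
        baseline_loss=baseline, per_type_val_loss=per_type_val,
        n_train_residues=sum(X.shape[0] for X, _ in train_data.values()),
        n_val_residues=sum(X.shape[0] for X, _ in val_data.values()),
    )
    return model, report


def _train_net(X, M, val, hidden, hp, rng):
    """Adam-train one per-type net; record masked loss after every epoch."""
    d = X.shape[1]
    net = _init_net(d, hidden, rng)
    m = {k: np.zeros_like(v) for k, v in net.items()}
    v = {k: np.zeros_like(val_) for k, val_ in net.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    train_curve: list[float] = []
    val_curve: list[float] = []
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            Mb = M[idx]
            if not Mb.any():
                continue
            g, _ = _grads(net, X[idx], Mb)
            t += 1
            for k in net:
                m[k] = beta1 * m[k] + (1 - beta1) * g[k]
                v[k] = beta2 * v[k] + (1 - beta2) * g[k] ** 2
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                net[k] = net[k] - hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
        train_curve.append(masked_loss(net, X, M))
        val_curve.append(masked_loss(net, *val) if val is not None else float("nan"))
    return net, (train_curve, val_curve)


def _aggregate_curves(curves, train_data, val_data, epochs):
    """Observed-count-weighted mean loss per epoch across residue types."""
    epoch_train: list[float] = []
    epoch_val: list[float] = []
    for e in range(epochs):
        num = den = 0.0
        for rt, (tc, _) in curves.items():
            w = float(np.sum(train_data[rt][1]))
            num += w * tc[e]
            den += w
        epoch_train.append(num / den if den else float("nan"))
        num = den = 0.0
        for rt, (_, vc) in curves.items():
            if rt not in val_data or np.isnan(vc[e]):
                continue
            w = float(np.sum(val_data[rt][1]))
            num += w * vc[e]
            den += w
        epoch_val.append(num / den if den else float("nan"))
    return epoch_train, epoch_val


# ---------------------------------------------------------------------------
# Orientation calibration
# ---------------------------------------------------------------------------

def calibrate_orientation(
        model: ShiftCryptModel,
        labeled: Iterable[tuple[ResidueVector, str]]) -> ShiftCryptModel:
    """Flip per-type outputs so helix maps low and sheet high, globally.

    ``labeled`` pairs encoded residues with secondary-structure classes
    ('H' helix, 'E' sheet, 'C' coil; coil examples are ignored here).  For
    each residue type, if the current mean value of helix examples exceeds
    that of sheet examples, the orientation flag toggles.  Idempotent:
    recalibrating an oriented model changes nothing.
    """
    acc: dict[str, dict[str, list[float]]] = {}
    for vec, label in labeled:
        if label not in ("H", "E"):
            continue
        z = model.bottleneck(vec)
        if z is None:
            continue
        acc.setdefault(vec.residue_type, {}).setdefault(label, []).append(z)
    for rt in model.nets:
        classes = acc.get(rt, {})
        if "H" not in classes or "E" not in classes:
            logger.warning("residue type %s: missing helix or sheet examples; "
                           "orientation left unchanged", rt)
            continue
        if float(np.mean(classes["H"])) > float(np.mean(classes["E"])):
            model.flip[rt] = not model.flip.get(rt, False)
    return model


def labeled_vectors(tables: Sequence[ShiftTable], labels: Sequence[str],
                    model: ShiftCryptModel) -> list[tuple[ResidueVector, str]]:
    """Encode labelled tables into (vector, class) pairs for calibration."""
    scheme = build_scheme(model.scheme_name)
    out = []
    for table, lab in zip(tables, labels):
        for res, cls in zip(table, lab):
            out.append((encode_residue(res, scheme, model.stats), cls))
    return out


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def transform(table: ShiftTable, model: ShiftCryptModel) -> ProfileRecord:
    """Compress every residue of a table into its profile value.

    A residue with no observed atom under the model's scheme, or whose type
    the model was not trained on, yields a missing value (None).
    """
    scheme = build_scheme(model.scheme_name)
    values: list[Optional[float]] = []
    warned: set[str] = set()
    for res in table:
        if res.residue_type not in model.nets:
            if res.residue_type not in warned:
                logger.warning("entry %s: residue type %s not in model; "
                               "values set to missing", table.entry_id,
                               res.residue_type)
                warned.add(res.residue_type)
            values.append(None)
            continue
        vec = encode_residue(res, scheme, model.stats)
        values.append(model.bottleneck(vec))
    return ProfileRecord(
        entry_id=table.entry_id,
        seq_ids=[r.seq_id for r in table],
        sequence=table.sequence,
        values=values,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: ShiftCryptModel, path: str) -> None:
    """Write a model as a self-describing JSON archive (exact float repr)."""
    obj = {
        "format": MODEL_FORMAT,
        "version": model.version,
        "scheme": model.scheme_name,
        "hyperparams": model.hyperparams,
        "flip": {rt: bool(f) for rt, f in model.flip.items()},
        "stats": {
            f"{rt} {atom}": [st.mean, st.std, st.lower, st.upper, st.count]
            for (rt, atom), st in model.stats.stats.items()
        },
        "nets": {
            rt: {k: net[k].tolist() for k in _PARAM_NAMES}
            for rt, net in model.nets.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_model(path: str) -> ShiftCryptModel:
    """Load a model archive written by :func:`save_model`."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted model file {path!r}: {exc}") from exc
    if not isinstance(obj, dict) or obj.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path!r} is not a shiftcrypt model file")
    if obj.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model version mismatch: file has {obj.get('version')!r}, "
            f"this package reads {MODEL_VERSION!r}")
    stats = NormStats(obj["scheme"])
    for key, row in obj["stats"].items():
        rt, atom = key.split(" ", 1)
        stats.stats[(rt, atom)] = AtomStats(row[0], row[1], row[2], row[3],
                                            int(row[4]))
    nets = {
        rt: {k: np.asarray(net[k], dtype=float) for k in _PARAM_NAMES}
        for rt, net in obj["nets"].items()
    }
    return ShiftCryptModel(
        scheme_name=obj["scheme"], stats=stats, nets=nets,
        flip={rt: bool(f) for rt, f in obj["flip"].items()},
        hyperparams=obj.get("hyperparams", {}), version=obj["version"],
    )
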