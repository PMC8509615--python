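"""Training harness: a seeded NumPy CNN with Adam and cross-entropy,
epoch-budgeted early stopping on validation loss, per-image -> per-molecule
probability pooling, replicate averaging, and grid sweeps.

The checkpoint reported by :func:`train_model` is the epoch with minimum
validation loss within the epoch budget (default 30). Replicate runs differ
only in seed and are averaged field-wise (default N = 3).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from snapqsar import metrics as metrics_mod
from snapqsar.metrics import MetricReport

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainedRun",
    "train_model",
    "aggregate_molecule",
    "evaluate_split",
    "replicate_average",
    "run_sweep",
    "load_manifest_images",
]


# ---------------------------------------------------------------------------
# layers


class _Conv:
    """3x3/1x1/5x5 same-padding convolution, stride 1, via im2col."""

    def __init__(self, c_in, c_out, k, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in, k, k)).astype(np.float64)
        self.b = np.zeros(c_out)
        self.k = k

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x):
        from numpy.lib.stride_tricks import sliding_window_view

        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # win: (n, c, h, w, k, k) -> cols (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        self._cols, self._shape = cols, (n, c, h, w)
        wm = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wm.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w = self._shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.dW = (dyf.T @ self._cols).reshape(self.W.shape)
        self.db = dyf.sum(axis=0)
        dcols = dyf @ self.W.reshape(self.W.shape[0], -1)
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class _ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        out = xr.max(axis=-1)
        # argmax keeps the first max per window -> deterministic gradient
        first = np.argmax(xr, axis=-1)
        m = np.zeros_like(xr)
        np.put_along_axis(m, first[..., None], 1.0, axis=-1)
        self._mask, self._shape = m, (n, c, h, w)
        return out

    def backward(self, dy):
        n, c, h, w = self._shape
        d = self._mask * dy[..., None]
        return d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class _GlobalMaxPool:
    """Global spatial max: suits presence-style features (a localized atom
    color) far better than average pooling at these tiny resolutions."""

    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._arg = np.argmax(flat, axis=2)
        self._hw = (h, w)
        return flat.max(axis=2)

    def backward(self, dy):
        n, c = dy.shape
        h, w = self._hw
        d = np.zeros((n, c, h * w))
        np.put_along_axis(d, self._arg[..., None], dy[..., None], axis=2)
        return d.reshape(n, c, h, w)


class _Dense:
    def __init__(self, d_in, d_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_out, d_in))
        self.b = np.zeros(d_out)

    def params(self):
        return [("W", self), ("b", self)]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W


class _Inception:
    """Minimal inception block: parallel 1x1, 1x1->3x3 and 1x1->5x5 branches
    concatenated along channels."""

    def __init__(self, c_in, rng, o1=8, r3=8, o3=12, r5=4, o5=4):
        self.b1 = [_Conv(c_in, o1, 1, rng)]
        self.b3 = [_Conv(c_in, r3, 1, rng), _ReLU(), _Conv(r3, o3, 3, rng)]
        self.b5 = [_Conv(c_in, r5, 1, rng), _ReLU(), _Conv(r5, o5, 5, rng)]
        self.c_out = o1 + o3 + o5
        self._splits = (o1, o1 + o3)

    def params(self):
        out = []
        for branch in (self.b1, self.b3, self.b5):
            for layer in branch:
                out.extend(layer.params())
        return out

    def forward(self, x):
        outs = []
        for branch in (self.b1, self.b3, self.b5):
            h = x
            for layer in branch:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        s1, s2 = self._splits
        parts = (dy[:, :s1], dy[:, s1:s2], dy[:, s2:])
        dx = 0.0
        for branch, dpart in zip((self.b1, self.b3, self.b5), parts):
            g = dpart
            for layer in reversed(branch):
                g = layer.backward(g)
            dx = dx + g
        return dx


def _build_model(architecture: str, input_size: int, rng) -> list:
    if input_size % 8 != 0:
        raise ValueError("input_size must be divisible by 8")
    if architecture == "small_cnn":
        return [
            _Conv(3, 8, 3, rng), _ReLU(), _MaxPool2(),
            _Conv(8, 16, 3, rng), _ReLU(), _MaxPool2(),
            _Conv(16, 32, 3, rng), _ReLU(), _MaxPool2(),
            _GlobalMaxPool(), _Dense(32, 2, rng),
        ]
    if architecture == "googlenet_like":
        inc = _Inception(8, rng)
        return [
            _Conv(3, 8, 3, rng), _ReLU(), _MaxPool2(),
            inc, _ReLU(), _MaxPool2(),
            _Conv(inc.c_out, 32, 3, rng), _ReLU(), _MaxPool2(),
            _GlobalMaxPool(), _Dense(32, 2, rng),
        ]
    raise ValueError(f"unknown architecture {architecture!r}")


def _forward(model, x):
    for layer in model:
        x = layer.forward(x)
    return x


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(probs, y):
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y],
                                         1e-12, None))))


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        self.v = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, obj) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            setattr(obj, name, getattr(obj, name)
                    - self.lr * mhat / (np.sqrt(vhat) + self.eps))


# ---------------------------------------------------------------------------
# data loading


def load_manifest_images(manifest: pd.DataFrame, input_size: int = 32,
                         cache: dict | None = None) -> np.ndarray:
    """Load manifest PNGs as a float array (n, 3, s, s) in [0, 1],
    downsampled by block averaging (PIL bilinear for awkward sizes)."""
    from PIL import Image

    arrays = []
    for path in manifest["image_path"]:
        key = (path, input_size)
        if cache is not None and key in cache:
            arrays.append(cache[key])
            continue
        img = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64)
        h = img.shape[0]
        if h % input_size == 0:
            b = h // input_size
            small = img.reshape(input_size, b, input_size, b, 3).mean(axis=(1, 3))
        else:
            pil = Image.fromarray(img.astype(np.uint8)).resize(
                (input_size, input_size), Image.BILINEAR)
            small = np.asarray(pil, dtype=np.float64)
        arr = (small / 255.0).transpose(2, 0, 1)
        if cache is not None:
            cache[key] = arr
        arrays.append(arr)
    return np.stack(arrays)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-3
    batch_size: int = 16
    max_epochs: int = 30
    seed: int = 0
    architecture: str = "small_cnn"
    replicate_count: int = 3
    input_size: int = 32
    patience: int | None = None  # None: always run the full epoch budget
    aggregate: str = "mean"  # image -> molecule pooling: mean | median | max
    cutoff_policy: str = "youden_self"  # or youden_valid

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainedRun:
    config: TrainConfig
    loss_train: list[float]
    loss_valid: list[float]
    selected_epoch: int  # 0-based index into the history
    image_probs: dict[str, pd.DataFrame]  # split -> (compound_id, label, prob)
    reports: dict[str, MetricReport] = field(default_factory=dict)

    @property
    def best_loss_valid(self) -> float:
        return self.loss_valid[self.selected_epoch]


def _check_no_leakage(manifest: pd.DataFrame) -> None:
    per_mol = manifest.groupby("compound_id")["split"].nunique()
    leaky = per_mol[per_mol > 1]
    if len(leaky):
        raise ValueError(
            f"molecules present in multiple splits: {list(leaky.index)[:5]}")


def train_model(manifest: pd.DataFrame, config: TrainConfig,
                image_cache: dict | None = None) -> TrainedRun:
    """Train on the manifest's train split, early-stop on validation loss,
    and score every split's images with the selected checkpoint."""
    _check_no_leakage(manifest)
    parts = {name: manifest[manifest["split"] == name]
             for name in ("train", "valid", "test", "foldout")}
    for name in ("train", "valid"):
        if parts[name]["label"].nunique() < 2:
            raise ValueError(f"{name} split needs both classes present")
    x_train = load_manifest_images(parts["train"], config.input_size, image_cache)
    y_train = parts["train"]["label"].to_numpy(dtype=int)
    x_valid = load_manifest_images(parts["valid"], config.input_size, image_cache)
    y_valid = parts["valid"]["label"].to_numpy(dtype=int)
    if config.batch_size > len(x_train):
        raise ValueError("batch_size exceeds the training split size")

    rng = np.random.default_rng(config.seed)
    model = _build_model(config.architecture, config.input_size, rng)
    params = [p for layer in model for p in layer.params()]
    opt = _Adam(params, config.learning_rate)

    def full_loss(x, y):
        probs = _softmax(_forward(model, x))
        return _xent(probs, y)

    loss_train_hist: list[float] = []
    loss_valid_hist: list[float] = []
    best_state, best_loss, best_epoch = None, np.inf, -1
    since_best = 0
    for epoch in range(config.max_epochs):
        idx = rng.permutation(len(x_train))
        for start in range(0, len(idx), config.batch_size):
            batch = idx[start:start + config.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            probs = _softmax(_forward(model, xb))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            g = dlogits
            for layer in reversed(model):
                g = layer.backward(g)
            opt.step()
        lt = full_loss(x_train, y_train)
        lv = full_loss(x_valid, y_valid)
        loss_train_hist.append(lt)
        loss_valid_hist.append(lv)
        logger.info("epoch %d loss_train=%.4f loss_valid=%.4f", epoch, lt, lv)
        if lv < best_loss - 1e-12:
            best_loss, best_epoch, since_best = lv, epoch, 0
            best_state = [(name, obj, getattr(obj, name).copy())
                          for name, obj in params]
        else:
            since_best += 1
            if config.patience is not None and since_best >= config.patience:
                break

    for name, obj, value in best_state:
        setattr(obj, name, value)

    image_probs: dict[str, pd.DataFrame] = {}
    for name, part in parts.items():
        if part.empty:
            continue
        x = (x_train if name == "train"
             else x_valid if name == "valid"
             else load_manifest_images(part, config.input_size, image_cache))
        probs = _softmax(_forward(model, x))[:, 1]
        image_probs[name] = pd.DataFrame({
            "compound_id": part["compound_id"].to_numpy(),
            "label": part["label"].to_numpy(dtype=int),
            "prob": probs,
        })
    return TrainedRun(config=config, loss_train=loss_train_hist,
                      loss_valid=loss_valid_hist, selected_epoch=best_epoch,
                      image_probs=image_probs)


def aggregate_molecule(image_probs: Sequence[float],
                       how: str = "mean") -> float:
    """Pool per-image probabilities into one per-molecule probability."""
    probs = np.asarray(image_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("cannot aggregate an empty probability list")
    if how == "mean":
        return float(probs.mean())
    if how == "median":
        return float(np.median(probs))
    if how == "max":
        return float(probs.max())
    raise ValueError(f"unknown aggregation {how!r}")


def molecule_table(run: TrainedRun, split: str) -> pd.DataFrame:
    """Per-molecule probabilities and labels for one split."""
    if split not in run.image_probs:
        raise ValueError(f"no predictions for split {split!r}")
    df = run.image_probs[split]
    rows = []
    for cid, grp in df.groupby("compound_id", sort=True):
        rows.append({
            "compound_id": cid,
            "label": int(grp["label"].iloc[0]),
            "prob": aggregate_molecule(grp["prob"], run.config.aggregate),
        })
    return pd.DataFrame(rows)


def evaluate_split(run: TrainedRun, split: str,
                   cutoff_policy: str | None = None) -> MetricReport:
    """Molecule-level metric report for one split.

    ``youden_self`` picks the Youden cutoff on the evaluated split itself;
    ``youden_valid`` transfers the validation-split cutoff.
    """
    policy = cutoff_policy or run.config.cutoff_policy
    mols = molecule_table(run, split)
    cutoff = None
    if policy == "youden_valid" and split != "valid":
        vmols = molecule_table(run, "valid")
        if vmols["label"].nunique() == 2:
            cutoff, _ = metrics_mod.youden_cutoff(vmols["prob"], vmols["label"])
    elif policy not in ("youden_self", "youden_valid"):
        raise ValueError(f"unknown cutoff policy {policy!r}")
    report = metrics_mod.full_report(mols["prob"].to_numpy(),
                                     mols["label"].to_numpy(), cutoff=cutoff)
    report.loss_train = run.loss_train[run.selected_epoch]
    report.loss_valid = run.loss_valid[run.selected_epoch]
    if split in run.image_probs:
        df = run.image_probs[split]
        p = np.clip(df["prob"].to_numpy(), 1e-12, 1 - 1e-12)
        y = df["label"].to_numpy()
        report.loss_test = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    run.reports[split] = report
    return report


def replicate_average(reports: Sequence[MetricReport],
                      configs: Sequence[TrainConfig] | None = None
                      ) -> MetricReport:
    """Field-wise arithmetic mean of replicate metric reports."""
    if not reports:
        raise ValueError("need at least one report")
    if configs is not None:
        base = [replace(c, seed=0) for c in configs]
        if any(c != base[0] for c in base):
            raise ValueError("replicate reports have mixed configurations")
    avg = MetricReport(n=reports[0].n)
    for name in MetricReport.NUMERIC_FIELDS:
        values = np.array([getattr(r, name) for r in reports], dtype=float)
        setattr(avg, name, float(np.nanmean(values))
                if not np.all(np.isnan(values)) else float("nan"))
    avg.degenerate_flags = sorted({f for r in reports
                                   for f in r.degenerate_flags})
    return avg


# ---------------------------------------------------------------------------
# sweeps


def _grid_points(grid: dict) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def run_sweep(molecules, conformers, grid: dict, base_config: TrainConfig,
              workdir: str | Path, split_seed: int = 0,
              foldout_fraction: float = 0.0, image_size: int = 256,
              results_path: str | Path | None = None) -> pd.DataFrame:
    """Grid sweep over any of theta / ratios / learning_rate / batch_size /
    background; one replicate-averaged row per grid point.

    Rows already present in ``results_path`` (matched on the serialized grid
    point) are skipped, making an interrupted sweep resumable.
    """
    from snapqsar.assay_prep import SplitPlan, split_dataset
    from snapqsar.snapshot_render import SnapshotSpec, generate_snapshots

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    results_path = Path(results_path) if results_path else workdir / "sweep.csv"
    done: dict[str, dict] = {}
    if results_path.exists():
        prev = pd.read_csv(results_path)
        done = {row["grid_point"]: row.to_dict()
                for _, row in prev.iterrows()}

    image_cache: dict = {}
    rows = []
    for point in _grid_points(grid):
        key = json.dumps(point, sort_keys=True)
        if key in done:
            rows.append(done[key])
            continue
        theta = tuple(point.get("theta", (195.0, 195.0, 195.0)))
        ratios = tuple(point.get("ratios", (1, 1, 1)))
        background = point.get("background", "white")
        cfg = replace(base_config,
                      learning_rate=point.get("learning_rate",
                                              base_config.learning_rate),
                      batch_size=point.get("batch_size",
                                           base_config.batch_size))

        plan = SplitPlan(ratios=ratios, foldout_fraction=foldout_fraction,
                         seed=split_seed)
        split_mols = split_dataset(molecules, plan)
        info = {m.compound_id: {"split": m.split, "label": m.label}
                for m in split_mols}
        theta_tag = "x".join(f"{t:g}" for t in theta)
        bg_tag = str(background).replace(" ", "_")
        img_dir = workdir / f"images_{theta_tag}_{bg_tag}"
        spec = SnapshotSpec(theta=theta, image_size=image_size,
                            background=background)
        manifest = generate_snapshots(conformers, spec, img_dir,
                                      molecule_info=info, overwrite=False)

        reports_v, reports_t, configs = [], [], []
        for r in range(base_config.replicate_count):
            rcfg = replace(cfg, seed=base_config.seed + r)
            run = train_model(manifest, rcfg, image_cache)
            reports_v.append(evaluate_split(run, "valid"))
            reports_t.append(evaluate_split(run, "test"))
            configs.append(rcfg)
        avg_v = replicate_average(reports_v, configs)
        avg_t = replicate_average(reports_t, configs)

        row = {"grid_point": key, "theta": theta_tag,
               "ratios": ":".join(map(str, ratios)),
               "background": str(background),
               "learning_rate": cfg.learning_rate,
               "batch_size": cfg.batch_size,
               "n_replicates": base_config.replicate_count}
        for name in MetricReport.NUMERIC_FIELDS:
            row[f"valid_{name}"] = getattr(avg_v, name)
            row[f"test_{name}"] = getattr(avg_t, name)
        rows.append(row)
        pd.DataFrame(rows).to_csv(results_path, index=False)
    table = pd.DataFrame(rows)
    table.to_csv(results_path, index=False)
    return table
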