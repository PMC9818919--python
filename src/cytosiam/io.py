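"""Dataset readers/writers, checkpoint persistence, and run configuration.

Datasets live on disk as one PNG (or TIFF) per cell under
``<root>/<label_name>/<index>.png`` together with a ``manifest.csv``
listing (filepath, label_name, label_id, split).  Checkpoints are numpy
``.npz`` archives with the architecture config and a format version
embedded, so loads fail loudly on mismatched formats or shapes.
"""

from __future__ import annotations

import json
import zipfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .network import EncoderParams, NetworkConfig
from .optim import AdamState
from .synthgen import LabeledDataset

CHECKPOINT_VERSION = 1
_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


# --------------------------------------------------------------------------
# image datasets
# --------------------------------------------------------------------------

def write_image_dataset(dataset: LabeledDataset, root, splits=None) -> Path:
    """Write PNGs under per-class directories plus a manifest.csv.

    ``splits`` optionally maps each image index to "train"/"val";
    unlisted images are marked "unsplit".  Pixels are quantised to 8 bit
    only here; in memory everything stays real-valued in [0, 1].
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    per_class_counter = {}
    for i in range(len(dataset)):
        label = int(dataset.labels[i])
        name = dataset.label_names[label]
        (root / name).mkdir(exist_ok=True)
        idx = per_class_counter.get(label, 0)
        per_class_counter[label] = idx + 1
        rel = f"{name}/{idx:05d}.png"
        arr = np.clip(dataset.images[i] * 255.0 + 0.5, 0, 255
                      ).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(root / rel)
        split = "unsplit" if splits is None else splits.get(i, "unsplit")
        rows.append((rel, name, label, split))
    manifest = pd.DataFrame(
        rows, columns=["filepath", "label_name", "label_id", "split"]
    )
    manifest.to_csv(root / "manifest.csv", index=False)
    return root / "manifest.csv"


def _load_image(path: Path, image_size: int | None):
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if image_size is not None and im.size != (image_size, image_size):
                im = im.resize((image_size, image_size), Image.BILINEAR)
            return np.asarray(im, dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise FileNotFoundError(f"image file missing: {path}") from None
    except OSError as exc:
        raise OSError(f"unreadable image {path}: {exc}") from exc


def read_image_dataset(path, image_size: int | None = None,
                       split: str | None = None) -> LabeledDataset:
    """Load a dataset from a manifest CSV or a class-per-directory tree.

    With a manifest, labels follow its label_id column and ``split``
    optionally restricts to one split.  With a bare directory tree,
    label ids follow the sorted directory names.  Images are decoded to
    [0, 1] reals and bilinearly resized to ``image_size`` when given.
    """
    path = Path(path)
    manifest_path = path if path.suffix == ".csv" else path / "manifest.csv"
    if manifest_path.exists():
        root = manifest_path.parent
        manifest = pd.read_csv(manifest_path)
        if split is not None:
            manifest = manifest[manifest["split"] == split]
        if manifest.empty:
            raise ValueError(f"no images selected from {manifest_path}")
        n_classes = int(manifest["label_id"].max()) + 1
        names = [None] * n_classes
        for _, row in manifest.iterrows():
            names[int(row.label_id)] = str(row.label_name)
        if any(n is None for n in names):
            raise ValueError("manifest label_ids are not dense from 0")
        images = [
            _load_image(root / str(row.filepath), image_size)
            for _, row in manifest.iterrows()
        ]
        labels = manifest["label_id"].to_numpy(dtype=np.int64)
        return LabeledDataset(np.stack(images), labels, names)

    if not path.is_dir():
        raise FileNotFoundError(f"no manifest or directory at {path}")
    class_dirs = sorted(
        d for d in path.iterdir()
        if d.is_dir() and any(
            f.suffix.lower() in _IMAGE_SUFFIXES for f in d.iterdir()
        )
    )
    if not class_dirs:
        raise ValueError(f"no class directories with images under {path}")
    images, labels, names = [], [], []
    for label, d in enumerate(class_dirs):
        names.append(d.name)
        for f in sorted(d.iterdir()):
            if f.suffix.lower() in _IMAGE_SUFFIXES:
                images.append(_load_image(f, image_size))
                labels.append(label)
    return LabeledDataset(
        np.stack(images), np.asarray(labels, dtype=np.int64), names
    )


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(params: EncoderParams, config: NetworkConfig, path,
                    adam_state: AdamState | None = None,
                    epoch: int | None = None) -> None:
    """Persist parameters (and optionally optimizer state) to ``path``.

    The round trip is bitwise exact on every tensor.
    """
    arrays = {f"param/{n}": a for n, a in params.named_arrays()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": config.to_dict(),
        "epoch": epoch,
        "has_adam": adam_state is not None,
        "adam_t": adam_state.t if adam_state is not None else 0,
    }
    if adam_state is not None:
        for n, _ in params.named_arrays():
            arrays[f"adam_v/{n}"] = adam_state.V[n]
            arrays[f"adam_s/{n}"] = adam_state.S[n]
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, with_adam: bool = False):
    """Load (params, config) — or (params, config, adam_state, epoch)
    with ``with_adam`` — raising cleanly on corrupt or alien files."""
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except (OSError, ValueError, zlib.error, EOFError,
            zipfile.BadZipFile) as exc:
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}"
                         ) from exc
    if "__meta__" not in data:
        raise ValueError(f"{path} is not a cytosiam checkpoint")
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint format version {meta.get('version')} is not "
            f"supported (expected {CHECKPOINT_VERSION}); no silent "
            "migration is attempted"
        )
    config = NetworkConfig.from_dict(meta["config"])

    def grab(prefix, name):
        key = f"{prefix}/{name}"
        if key not in data:
            raise ValueError(f"checkpoint missing tensor {key}")
        return data[key]

    n_conv = len(config.conv_channels)
    params = EncoderParams(
        conv_kernels=[grab("param", f"conv{i}.kernel")
                      for i in range(n_conv)],
        conv_biases=[grab("param", f"conv{i}.bias") for i in range(n_conv)],
        enc_weight=grab("param", "enc.weight"),
        enc_bias=grab("param", "enc.bias"),
        head_weights=[grab("param", f"head{i}.weight") for i in range(5)],
        head_biases=[grab("param", f"head{i}.bias") for i in range(5)],
    )
    params.validate(config)
    if not with_adam:
        return params, config
    if not meta.get("has_adam"):
        raise ValueError(f"checkpoint {path} holds no optimizer state")
    state = AdamState(
        V={n: grab("adam_v", n) for n, _ in params.named_arrays()},
        S={n: grab("adam_s", n) for n, _ in params.named_arrays()},
        t=int(meta["adam_t"]),
    )
    return params, config, state, meta.get("epoch")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_RUNCONFIG_DEFAULTS = {
    "seed": 0,
    "image_size": 50,
    "in_channels": 3,
    "conv_channels": [8, 16, 32, 64],
    "kernel_size": 3,
    "encoding_dim": 64,
    "dense_widths": [64, 32, 16, 8, 1],
    "head_mode": "concat",
    "margin_triplet": 0.2,
    "objective": "pair_nll",
    "eta": 1e-3,
    "beta1": 0.9,
    "beta2": 0.999,
    "adam_eps": 1e-8,
    "n_epochs": 30,
    "pairs_per_class": 32,
    "batch_size": 32,
    "val_fraction": 0.2,
    "gallery_k_per_class": 10,
}


@dataclass
class RunConfig:
    """All pipeline knobs in one validated bag.

    Unknown keys are rejected, so a typo in a config file fails fast
    instead of silently falling back to a default.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(_RUNCONFIG_DEFAULTS)
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; known keys are "
                f"{sorted(_RUNCONFIG_DEFAULTS)}"
            )
        merged = dict(_RUNCONFIG_DEFAULTS)
        merged.update(self.values)
        for key, default in _RUNCONFIG_DEFAULTS.items():
            got = merged[key]
            if isinstance(default, (int, float)) and \
                    not isinstance(default, bool):
                if not isinstance(got, (int, float)):
                    raise ValueError(f"config key {key} must be numeric")
            if isinstance(default, str) and not isinstance(got, str):
                raise ValueError(f"config key {key} must be a string")
            if isinstance(default, list) and not isinstance(got, list):
                raise ValueError(f"config key {key} must be a list")
        self.values = merged

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls(values=loaded)

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            input_size=int(self["image_size"]),
            in_channels=int(self["in_channels"]),
            conv_channels=tuple(self["conv_channels"]),
            kernel_size=int(self["kernel_size"]),
            encoding_dim=int(self["encoding_dim"]),
            dense_widths=tuple(self["dense_widths"]),
            margin_triplet=float(self["margin_triplet"]),
            head_mode=str(self["head_mode"]),
        )

    def adam_hyper(self):
        from .optim import AdamHyper

        return AdamHyper(
            eta=float(self["eta"]),
            beta1=float(self["beta1"]),
            beta2=float(self["beta2"]),
            adam_eps=float(self["adam_eps"]),
        )
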