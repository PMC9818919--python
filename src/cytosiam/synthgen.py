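"""Seeded generator of synthetic labeled cell-image datasets.

Emulates single-cell crops from stained bone-marrow smears: a roughly
elliptical nucleus inside a halo of cytoplasm on a pale background, with
class-specific morphology (nucleus size and eccentricity, nucleus and
cytoplasm hue, granularity, texture noise) and an arbitrarily skewed
class-frequency vector.  Everything is a pure function of its arguments
and an integer seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Acronyms of the 21 morphologic cell classes of the public bone-marrow
#: cytology benchmark, in its published ordering.
BONE_MARROW_CLASS_ACRONYMS = (
    "ABE", "ART", "BAS", "BLA", "EBO", "EOS", "FGC", "HAC", "KSC", "LYI",
    "LYT", "MMZ", "MON", "MYB", "NGB", "NGS", "NIF", "PEB", "PLM", "PMO",
    "OTH",
)

_MAX_REJECTION_ATTEMPTS = 1000


@dataclass(frozen=True)
class ClassPhenotype:
    """Morphologic recipe for rendering one cell class."""

    class_id: int
    name: str
    nucleus_radius_frac: float      # fraction of image width, in (0.05, 0.45)
    nucleus_eccentricity: float     # in [0, 1)
    nucleus_color: tuple            # RGB in [0,1]^3
    cytoplasm_color: tuple          # RGB in [0,1]^3
    granule_count: int
    granule_radius_px: float
    texture_noise_sd: float

    def feature_vector(self) -> np.ndarray:
        """Normalised feature vector used for phenotype-separation distances."""
        return np.array(
            [
                self.nucleus_radius_frac / 0.45,
                self.nucleus_eccentricity,
                *self.nucleus_color,
                *self.cytoplasm_color,
                self.granule_count / 30.0,
                self.granule_radius_px / 3.0,
                self.texture_noise_sd / 0.1,
            ]
        )


@dataclass
class LabeledDataset:
    """Images plus integer class labels and label names.

    Images are stored stacked as a single float array of shape
    ``(n, size, size, 3)`` with values in [0, 1].
    """

    images: np.ndarray
    labels: np.ndarray
    label_names: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if len(self.labels) and self.labels.max() >= len(self.label_names):
            raise ValueError("label id exceeds label_names")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=np.int64)
        return LabeledDataset(
            images=self.images[indices],
            labels=self.labels[indices],
            label_names=list(self.label_names),
            seed=self.seed,
        )


def _draw_phenotype(class_id, name, rng, center, separation):
    """One candidate phenotype, shrunk toward the library center.

    ``separation`` in [0, 1] scales how far class recipes spread from a
    library-wide random center: 0 makes classes nearly identical, 1 gives
    the full morphology range.
    """
    raw = np.array(
        [
            rng.uniform(0.12, 0.40),          # nucleus radius fraction
            rng.uniform(0.0, 0.7),            # eccentricity
            *rng.uniform(0.05, 0.75, 3),      # nucleus color (darker)
            *rng.uniform(0.35, 0.95, 3),      # cytoplasm color (paler)
            rng.integers(0, 29),              # granule count
            rng.uniform(0.8, 2.5),            # granule radius px
            rng.uniform(0.005, 0.05),         # texture noise sd
        ]
    )
    mixed = center + separation * (raw - center)
    return ClassPhenotype(
        class_id=class_id,
        name=name,
        nucleus_radius_frac=float(np.clip(mixed[0], 0.06, 0.44)),
        nucleus_eccentricity=float(np.clip(mixed[1], 0.0, 0.95)),
        nucleus_color=tuple(np.clip(mixed[2:5], 0.0, 1.0)),
        cytoplasm_color=tuple(np.clip(mixed[5:8], 0.0, 1.0)),
        granule_count=int(round(max(mixed[8], 0.0))),
        granule_radius_px=float(max(mixed[9], 0.5)),
        texture_noise_sd=float(max(mixed[10], 0.0)),
    )


def make_phenotype_library(
    n_classes: int, seed: int, separation: float = 0.8
) -> list:
    """Build ``n_classes`` mutually distinguishable class phenotypes.

    Names cycle through the 21 bone-marrow class acronyms.  Any two
    phenotypes differ by at least ``0.5 * separation`` in normalised
    feature distance, enforced by rejection sampling (at most 1000
    attempts per class).
    """
    if not 1 <= n_classes <= 64:
        raise ValueError(f"n_classes must be in [1, 64], got {n_classes}")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # library-wide center, drawn once, in the raw layout of _draw_phenotype
    raw_center = np.array(
        [
            rng.uniform(0.12, 0.40),
            rng.uniform(0.0, 0.7),
            *rng.uniform(0.05, 0.75, 3),
            *rng.uniform(0.35, 0.95, 3),
            rng.uniform(0, 29),
            rng.uniform(0.8, 2.5),
            rng.uniform(0.005, 0.05),
        ]
    )

    min_dist = 0.5 * separation
    library: list = []
    for cid in range(n_classes):
        name = BONE_MARROW_CLASS_ACRONYMS[cid % len(BONE_MARROW_CLASS_ACRONYMS)]
        if n_classes > len(BONE_MARROW_CLASS_ACRONYMS):
            name = f"{name}{cid // len(BONE_MARROW_CLASS_ACRONYMS) + 1}"
        for _ in range(_MAX_REJECTION_ATTEMPTS):
            cand = _draw_phenotype(cid, name, rng, raw_center, separation)
            if n_classes == 1 or all(
                np.linalg.norm(cand.feature_vector() - p.feature_vector())
                >= min_dist
                for p in library
            ):
                library.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place phenotype {cid} after "
                f"{_MAX_REJECTION_ATTEMPTS} attempts; lower separation"
            )
    return library


def render_cell(
    phenotype: ClassPhenotype, image_size: int, seed: int
) -> np.ndarray:
    """Render one cell crop as a float image in [0,1]^{S×S×3}.

    Background, cytoplasm disc, rotated nucleus ellipse (soft ~1 px
    antialiased edges), granule specks, then additive Gaussian texture
    noise, clipped to [0, 1].  Deterministic in (phenotype, size, seed).
    """
    if image_size < 16:
        raise ValueError("image_size must be >= 16")
    rng = np.random.default_rng(seed)
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    img = np.empty((s, s, 3))
    img[...] = np.array([0.93, 0.91, 0.95])  # pale slide background

    # center jitter bounded so the cell stays inside the crop
    cx = s / 2 + rng.uniform(-0.06, 0.06) * s
    cy = s / 2 + rng.uniform(-0.06, 0.06) * s

    nuc_r = phenotype.nucleus_radius_frac * s
    cyt_r = min(nuc_r * 1.7, 0.47 * s)

    def soft_disk(dist, radius):
        # ~1 px smooth edge; piecewise constant away from the boundary
        return np.clip(radius + 0.5 - dist, 0.0, 1.0)

    d_cyt = np.hypot(xx - cx, yy - cy)
    a_cyt = soft_disk(d_cyt, cyt_r)[..., None]
    img = img * (1 - a_cyt) + np.asarray(phenotype.cytoplasm_color) * a_cyt

    # granules: small dark specks scattered in the cytoplasm annulus
    if phenotype.granule_count > 0:
        g_color = np.asarray(phenotype.cytoplasm_color) * 0.45
        for _ in range(phenotype.granule_count):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.2, 0.95) * cyt_r
            gx, gy = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            d_g = np.hypot(xx - gx, yy - gy)
            a_g = soft_disk(d_g, phenotype.granule_radius_px)[..., None]
            img = img * (1 - a_g) + g_color * a_g

    # nucleus: rotated ellipse, axes set by eccentricity e: b = a*sqrt(1-e^2)
    theta = rng.uniform(0, np.pi)
    e = phenotype.nucleus_eccentricity
    a_ax = nuc_r
    b_ax = max(nuc_r * np.sqrt(1.0 - e * e), 1.0)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    # approximate signed distance via normalised ellipse radius
    r_ell = np.sqrt((u / a_ax) ** 2 + (v / b_ax) ** 2)
    d_ell = (r_ell - 1.0) * min(a_ax, b_ax)
    a_nuc = np.clip(0.5 - d_ell, 0.0, 1.0)[..., None]
    img = img * (1 - a_nuc) + np.asarray(phenotype.nucleus_color) * a_nuc

    if phenotype.texture_noise_sd > 0:
        img = img + rng.normal(0.0, phenotype.texture_noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    library: list,
    class_counts,
    image_size: int = 50,
    seed: int = 0,
) -> LabeledDataset:
    """Render ``class_counts[c]`` images per class and shuffle them.

    Each image gets its own render seed derived from ``seed`` via a
    SeedSequence spawn, so datasets are reproducible bit for bit.
    """
    class_counts = list(class_counts)
    if len(class_counts) != len(library):
        raise ValueError(
            f"class_counts has {len(class_counts)} entries for "
            f"{len(library)} phenotypes"
        )
    if any(c < 1 for c in class_counts):
        raise ValueError("all class counts must be positive")
    total = int(sum(class_counts))
    ss = np.random.SeedSequence(seed)
    render_seeds = ss.generate_state(total + 1)
    shuffle_rng = np.random.default_rng(render_seeds[-1] % (2**31))

    images = np.empty((total, image_size, image_size, 3))
    labels = np.empty(total, dtype=np.int64)
    i = 0
    for pheno, count in zip(library, class_counts):
        for _ in range(count):
            images[i] = render_cell(
                pheno, image_size, int(render_seeds[i] % (2**31))
            )
            labels[i] = pheno.class_id
            i += 1
    order = shuffle_rng.permutation(total)
    return LabeledDataset(
        images=images[order],
        labels=labels[order],
        label_names=[p.name for p in library],
        seed=seed,
    )


def stratified_split_indices(
    dataset: LabeledDataset, val_fraction: float, seed: int = 0
):
    """Index sets (train, val) for a stratified split; see
    :func:`stratified_split`."""
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(dataset.labels == c)
        if len(idx) == 0:
            continue
        if len(idx) == 1:
            warnings.warn(
                f"class {dataset.label_names[c]!r} has a single example; "
                "assigned entirely to train",
                stacklevel=2,
            )
            train_idx.extend(idx)
            continue
        n_val = int(round(len(idx) * val_fraction))
        n_val = min(max(n_val, 1), len(idx) - 1)
        idx = rng.permutation(idx)
        val_idx.extend(int(i) for i in idx[:n_val])
        train_idx.extend(int(i) for i in idx[n_val:])
    return sorted(train_idx), sorted(val_idx)


def stratified_split(
    dataset: LabeledDataset, val_fraction: float, seed: int = 0
):
    """Split into (train, validation) preserving class proportions.

    Per class ``c`` with count ``n_c >= 2`` the validation set receives
    ``round(n_c * val_fraction)`` images, but at least one.  Singleton
    classes fall entirely into train with a warning.  The two index sets
    are disjoint by construction.
    """
    train_idx, val_idx = stratified_split_indices(dataset, val_fraction,
                                                  seed)
    return dataset.subset(train_idx), dataset.subset(val_idx)
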