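"""Synthetic multiparametric tumor phantoms with ground-truth labels.

The default geometry is an ellipsoidal "tumor" with three concentric tissue
shells — a necrotic core, a peri-necrotic rim and a viable outer shell —
whose radii are solved from the realized voxel radii so the hard fractions
hit their targets.  Per-voxel features are drawn from class-conditional
distributions over the five parameters (ADC, T2 pre/post, T2* pre/post);
only the ADC class means/SDs are literature-derived, the rest are synthetic
values chosen to reproduce a plausible ordering and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io_model import DEFAULT_PARAMS, MultiparametricStack
from .evaluate import TISSUE_ORDER, TissueFractions

__all__ = ["PhantomSpec", "generate_phantom", "halfmoon_embed", "DEFAULT_CLASS_PARAMS"]

#: Class-conditional (mean, SD) per parameter.  ADC values (1e-6 mm^2/s) are
#: literature-derived; T2/T2* values (ms) are synthetic but ordered so that
#: post-contrast relaxation drops most in perfused (viable) tissue.
DEFAULT_CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "necrotic": {
        "ADC": (1252.68, 628.48),
        "T2_pre": (80.0, 9.0),
        "T2_post": (74.0, 9.0),
        "T2star_pre": (30.0, 4.5),
        "T2star_post": (26.0, 4.5),
    },
    "peri-necrotic": {
        "ADC": (1132.2, 466.72),
        "T2_pre": (62.0, 8.0),
        "T2_post": (48.0, 7.0),
        "T2star_pre": (24.0, 4.0),
        "T2star_post": (14.0, 3.5),
    },
    "viable": {
        "ADC": (598.46, 344.67),
        "T2_pre": (46.0, 7.0),
        "T2_post": (26.0, 5.0),
        "T2star_pre": (18.0, 3.5),
        "T2star_post": (6.0, 2.0),
    },
}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom realization."""

    shape: tuple[int, int, int] = (24, 24, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: str = "concentric_shells"
    fractions: tuple[float, ...] = (0.2, 0.3, 0.5)  # necrotic, peri-necrotic, viable
    class_params: dict = field(
        default_factory=lambda: {
            c: dict(v) for c, v in DEFAULT_CLASS_PARAMS.items()
        }
    )
    noise_multiplier: float = 1.0
    flip_rate: float = 0.0
    heavy_tails: bool = False  # Student-t (df=4) instead of normal draws
    #: draw the first two classes' (T2 pre, T2 post) coordinates from two
    #: interleaved crescent arcs instead of a Gaussian — an irregular,
    #: non-convex class boundary in parameter space (their configured T2
    #: means/SDs are ignored; ADC and T2* draws are unaffected)
    crescent_pair: bool = False
    mask_semiaxes_frac: float = 0.47
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("class fraction targets must sum to 1")
        if not 0.0 <= self.flip_rate < 0.5:
            raise ValueError("flip rate must lie in [0, 0.5)")
        for cls, params in self.class_params.items():
            for p, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {cls}/{p}")
        if self.noise_multiplier < 0:
            raise ValueError("noise multiplier must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["spacing"] = list(self.spacing)
        d["fractions"] = list(self.fractions)
        d["class_params"] = {
            c: {p: list(ms) for p, ms in v.items()} for c, v in self.class_params.items()
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["shape"] = tuple(d["shape"])
        d["spacing"] = tuple(d["spacing"])
        d["fractions"] = tuple(d["fractions"])
        d["class_params"] = {
            c: {p: tuple(ms) for p, ms in v.items()}
            for c, v in d["class_params"].items()
        }
        return cls(**d)


def _ellipsoid_radius(shape: tuple[int, int, int], semiaxes_frac: float) -> np.ndarray:
    center = (np.array(shape) - 1) / 2.0
    axes = np.maximum(np.array(shape) * semiaxes_frac, 1e-9)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return np.sqrt(r2)


def _shell_labels(
    radius: np.ndarray, mask: np.ndarray, fractions: tuple[float, ...]
) -> np.ndarray:
    """Assign concentric shell labels so realized fractions match targets.

    Thresholds are the empirical quantiles of the masked voxel radii at the
    cumulative fraction targets, which pins the realized hard fractions to
    within one voxel of the targets.
    """
    r = radius[mask]
    order = np.argsort(r, kind="stable")
    n = len(r)
    labels_flat = np.empty(n, dtype=int)
    bounds = np.cumsum(fractions)[:-1]
    cut = [int(round(b * n)) for b in bounds]
    start = 0
    for cls_idx, end in enumerate(list(cut) + [n]):
        labels_flat[order[start:end]] = cls_idx + 1
        start = end
    labels = np.zeros(radius.shape, dtype=int)
    labels[mask] = labels_flat
    return labels


def _draw_features(
    rng: np.random.Generator,
    labels_in_mask: np.ndarray,
    spec: PhantomSpec,
    class_names: tuple[str, ...],
    param_names: tuple[str, ...],
) -> np.ndarray:
    n = len(labels_in_mask)
    X = np.empty((n, len(param_names)))
    for cls_idx, cls in enumerate(class_names):
        sel = labels_in_mask == cls_idx + 1
        m = int(sel.sum())
        if m == 0:
            continue
        means = np.array([spec.class_params[cls][p][0] for p in param_names])
        sds = np.array(
            [spec.class_params[cls][p][1] for p in param_names]
        ) * spec.noise_multiplier
        if spec.heavy_tails:
            df = 4
            noise = rng.standard_t(df, size=(m, len(param_names)))
            noise *= np.sqrt((df - 2) / df)  # unit-variance t
        else:
            noise = rng.standard_normal((m, len(param_names)))
        X[sel] = means + noise * sds
        if spec.crescent_pair and cls_idx < 2:
            # interleaved arcs in the (T2 pre, T2 post) plane
            scale, cx, cy = 40.0, 60.0, 40.0
            jitter = 4.0 * spec.noise_multiplier
            t = rng.uniform(0, np.pi, m)
            if cls_idx == 0:
                arc = np.column_stack([np.cos(t), np.sin(t)])
            else:
                arc = np.column_stack([1.0 - np.cos(t), 0.5 - np.sin(t)])
            pts = np.array([cx, cy]) + scale * arc + rng.normal(0, jitter, (m, 2))
            X[sel, 1] = pts[:, 0]
            X[sel, 2] = pts[:, 1]
    return X


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MultiparametricStack, np.ndarray, TissueFractions]:
    """Generate a phantom stack, the truth label volume and truth fractions.

    Deterministic given ``spec.seed``.  Salt-and-pepper flips replace a
    voxel's feature draw with a draw from another class's distribution while
    leaving the truth label unchanged.  Truth fractions are computed from the
    realized labels (labels 1..3 = necrotic, peri-necrotic, viable).
    """
    if spec.geometry == "halfmoon_embed":
        stack, labels = halfmoon_embed(spec)
        fr = _fractions_from_labels(labels, stack.mask, ("class_1", "class_2"))
        return stack, labels, fr
    if spec.geometry not in ("concentric_shells", "two_blobs"):
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    class_names = tuple(spec.class_params)
    rng = np.random.default_rng(spec.seed)

    if spec.geometry == "concentric_shells":
        radius = _ellipsoid_radius(spec.shape, spec.mask_semiaxes_frac)
        mask = radius <= 1.0
        n = int(mask.sum())
        min_needed = int(np.ceil(1 / min(spec.fractions)))
        if n < max(min_needed, 3 * len(class_names)):
            raise ValueError(
                f"grid {spec.shape} too small to realize fraction targets "
                f"(only {n} masked voxels)"
            )
        labels = _shell_labels(radius, mask, spec.fractions)
    else:  # two_blobs: two contiguous half-slabs
        if len(class_names) < 2:
            raise ValueError("two_blobs needs >= 2 classes")
        mask = np.ones(spec.shape, dtype=bool)
        labels = np.ones(spec.shape, dtype=int)
        labels[spec.shape[0] // 2 :] = 2

    coords = np.argwhere(mask)
    lab_in_mask = labels[mask]
    X = _draw_features(rng, lab_in_mask, spec, class_names, DEFAULT_PARAMS)

    if spec.flip_rate > 0:
        n = len(lab_in_mask)
        n_flip = int(round(spec.flip_rate * n))
        flip_idx = rng.choice(n, size=n_flip, replace=False)
        K = len(class_names)
        for i in flip_idx:
            other = int(rng.integers(K - 1))
            if other >= lab_in_mask[i] - 1:
                other += 1
            fake = np.full(1, other + 1)
            X[i] = _draw_features(rng, fake, spec, class_names, DEFAULT_PARAMS)[0]

    maps = {
        p: _scatter(X[:, j], coords, spec.shape)
        for j, p in enumerate(DEFAULT_PARAMS)
    }
    stack = MultiparametricStack(maps=maps, mask=mask, spacing=spec.spacing)
    fr = _fractions_from_labels(labels, mask, class_names)
    return stack, labels, fr


def halfmoon_embed(spec: PhantomSpec) -> tuple[MultiparametricStack, np.ndarray]:
    """Two interleaved crescent manifolds in two of the five parameters.

    The two classes occupy contiguous half-slabs of the grid; the first two
    parameters carry the crescent coordinates, the remaining three are pure
    noise shared by both classes.  ``spec.noise_multiplier`` scales the
    crescent jitter (base SD 0.06 in crescent units).
    """
    rng = np.random.default_rng(spec.seed)
    mask = np.ones(spec.shape, dtype=bool)
    labels = np.ones(spec.shape, dtype=int)
    labels[spec.shape[0] // 2 :] = 2
    coords = np.argwhere(mask)
    lab = labels[mask]
    n0 = int((lab == 1).sum())
    n1 = int((lab == 2).sum())

    # interleaved crescents (upper arc vs shifted lower arc)
    t0 = rng.uniform(0, np.pi, n0)
    t1 = rng.uniform(0, np.pi, n1)
    arc0 = np.column_stack([np.cos(t0), np.sin(t0)])
    arc1 = np.column_stack([1.0 - np.cos(t1), 0.5 - np.sin(t1)])
    jitter_sd = 0.06 * spec.noise_multiplier
    pts = np.empty((n0 + n1, 2))
    pts[lab == 1] = arc0 + rng.normal(0, jitter_sd, (n0, 2))
    pts[lab == 2] = arc1 + rng.normal(0, jitter_sd, (n1, 2))

    # both crescent axes use the same scale (100 units per crescent unit) so
    # raw Euclidean distance preserves the manifold geometry; the remaining
    # parameters are low-amplitude pure noise.  Run this geometry with
    # standardization off, otherwise the noise parameters are inflated to
    # unit variance and swamp the crescent gap.
    X = np.empty((n0 + n1, len(DEFAULT_PARAMS)))
    X[:, 0] = pts[:, 0] * 100.0 + 900.0  # ADC-like offset
    X[:, 1] = pts[:, 1] * 100.0 + 60.0  # T2-like offset
    X[:, 2:] = rng.normal(30.0, 5.0, (n0 + n1, len(DEFAULT_PARAMS) - 2))

    maps = {
        p: _scatter(X[:, j], coords, spec.shape)
        for j, p in enumerate(DEFAULT_PARAMS)
    }
    stack = MultiparametricStack(maps=maps, mask=mask, spacing=spec.spacing)
    return stack, labels


def _scatter(values: np.ndarray, coords: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape)
    out[tuple(coords.T)] = values
    return out


def _fractions_from_labels(
    labels: np.ndarray, mask: np.ndarray, class_names: tuple[str, ...]
) -> TissueFractions:
    inside = labels[mask]
    n = len(inside)
    fr = {
        name: float((inside == k + 1).sum()) / n
        for k, name in enumerate(class_names)
    }
    return TissueFractions(fractions=fr, basis="hard", total_voxels=n)
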