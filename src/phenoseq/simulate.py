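"""Synthetic rosette time-lapse generator.

Produces labelled top-view growth sequences that emulate chamber imagery of
Arabidopsis-like rosettes: a soil-textured background, a centred rosette of
ellipse-shaped leaves added on a per-accession schedule, and per-plant nuisance
variability (germination offset, leaf-angle jitter, hue jitter).  Every frame
comes with a ground-truth foreground mask, which makes the generator usable
both as a benchmark source for the classification pipeline and as an oracle
for the segmentation stage.

Geometry is deterministic given ``(spec, day, seed)``: all randomness is drawn
from a per-plant stream, so the same plant rendered at two days shares its
background, leaf angles and hue, and the rosette only grows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "AccessionSpec",
    "PlantSequence",
    "linear_schedule",
    "default_accession_panel",
    "dynamics_pair_panel",
    "easy_accession_panel",
    "render_frame",
    "generate_sequences",
    "generate_dataset",
    "load_dataset",
    "class_separation_ratio",
]

#: reference canvas for which pixel-unit parameters are quoted
REFERENCE_CANVAS = 256

_SCHEDULE_LEN = 48  # days covered by a stored schedule; clamped beyond


def linear_schedule(base: int, rate: float, cap: int, length: int = _SCHEDULE_LEN) -> tuple[int, ...]:
    """Cumulative leaf-count schedule ``count(d) = min(base + floor(rate*d), cap)``."""
    return tuple(int(min(base + int(np.floor(rate * d)), cap)) for d in range(length))


@dataclass(frozen=True)
class AccessionSpec:
    """Phenotype parameters of one accession (genotyped line).

    Parameters
    ----------
    name:
        Text label of the accession.
    leaf_add_schedule:
        Non-decreasing cumulative leaf count indexed by day since germination.
    expansion_rate:
        Leaf major-axis growth in px/day at the 256 px reference canvas.
    leaf_aspect:
        Leaf length / width ratio, >= 1.
    hue_center, hue_jitter:
        Foreground HSV hue distribution, degrees (jitter is the per-plant s.d.).
    rotation_phyllotaxy:
        Angular offset between consecutive leaves, degrees.
    """

    name: str
    leaf_add_schedule: tuple[int, ...]
    expansion_rate: float
    leaf_aspect: float
    hue_center: float
    hue_jitter: float = 5.0
    rotation_phyllotaxy: float = 137.5
    #: asymptotic leaf length, as a fraction of the canvas (growth plateau)
    max_leaf_len_frac: float = 0.42

    def __post_init__(self) -> None:
        sched = tuple(int(c) for c in self.leaf_add_schedule)
        if any(b < a for a, b in zip(sched, sched[1:])):
            raise ValueError("leaf_add_schedule must be non-decreasing")
        if any(c < 0 for c in sched):
            raise ValueError("leaf_add_schedule must be non-negative")
        object.__setattr__(self, "leaf_add_schedule", sched)
        if self.expansion_rate <= 0:
            raise ValueError("expansion_rate must be positive")
        if self.leaf_aspect < 1:
            raise ValueError("leaf_aspect must be >= 1")
        if not (0.05 <= self.max_leaf_len_frac <= 0.5):
            raise ValueError("max_leaf_len_frac must be in [0.05, 0.5]")

    def leaf_count(self, day: int) -> int:
        """Cumulative leaf count at integer ``day`` (clamped schedule)."""
        if day < 0:
            return 0
        sched = self.leaf_add_schedule
        return sched[min(day, len(sched) - 1)]

    def static_params(self) -> tuple:
        """Appearance parameters that do not involve growth dynamics."""
        return (self.leaf_aspect, self.hue_center, self.hue_jitter, self.rotation_phyllotaxy)

    def temporal_params(self) -> tuple:
        return (self.leaf_add_schedule, self.expansion_rate, self.max_leaf_len_frac)


@dataclass
class PlantSequence:
    """One plant's ordered daily frames with its genotype label.

    ``genotype`` indexes the accession panel (0..L-1); ``day_index`` is
    strictly increasing, one entry per frame; ``truth_masks``, when present,
    aligns with ``frames``.
    """

    plant_id: str
    genotype: int
    frames: list[np.ndarray]
    day_index: list[int]
    truth_masks: list[np.ndarray] | None = None
    genotype_name: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.day_index):
            raise ValueError("frames and day_index length mismatch")
        if any(b <= a for a, b in zip(self.day_index, self.day_index[1:])):
            raise ValueError("day_index must be strictly increasing")
        shapes = {f.shape[:2] for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share height/width")
        if self.truth_masks is not None:
            if len(self.truth_masks) != len(self.frames):
                raise ValueError("truth_masks length mismatch")
            if any(m.shape[:2] != f.shape[:2] for m, f in zip(self.truth_masks, self.frames)):
                raise ValueError("truth_masks spatial size mismatch")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# accession panels

def default_accession_panel() -> list[AccessionSpec]:
    """The bundled 4-accession benchmark panel.

    The first two accessions share identical static appearance (leaf shape,
    hue, phyllotaxy) and differ only in their temporal parameters: one adds
    many leaves quickly but expands each slowly, the other adds few leaves
    and expands them fast.  Their total-area trajectories are matched within
    plant-to-plant variability, so area alone does not separate them — the
    discriminating signal is how the rosette is assembled over time.  The
    remaining two accessions share one intermediate schedule and differ in
    leaf shape (broad vs narrow), hue and phyllotaxy.
    """
    mid = linear_schedule(2, 0.42, 14)
    return [
        AccessionSpec("many-small", linear_schedule(2, 0.55, 16), 3.0, 2.4,
                      hue_center=96.0, hue_jitter=6.0),
        AccessionSpec("few-large", linear_schedule(2, 0.25, 8), 3.5, 2.4,
                      hue_center=96.0, hue_jitter=6.0),
        AccessionSpec("broad", mid, 3.4, 1.7, hue_center=112.0, hue_jitter=6.0),
        AccessionSpec("narrow", mid, 3.4, 3.1, hue_center=78.0, hue_jitter=6.0,
                      rotation_phyllotaxy=99.5),
    ]


def dynamics_pair_panel() -> list[AccessionSpec]:
    """Two accessions whose frames are pointwise look-alikes at different ages.

    Identical static appearance; the fast accession develops early and
    plateaus (smaller asymptotic leaves) at roughly the size the slow one
    only reaches at the end of the sequence, so most frames of either class
    have a look-alike somewhere in the other class's timeline and per-frame
    classification is poor, while the full growth trajectory (early-vigour
    vs steady growth) separates the two.  This is the panel for
    dynamics-only discrimination experiments.
    """
    return [
        AccessionSpec("tempo-fast", linear_schedule(2, 0.7, 12), 5.5, 2.4,
                      hue_center=96.0, hue_jitter=6.0, max_leaf_len_frac=0.28),
        AccessionSpec("tempo-slow", linear_schedule(2, 0.35, 12), 4.5, 2.4,
                      hue_center=96.0, hue_jitter=6.0),
    ]


def easy_accession_panel() -> list[AccessionSpec]:
    """A deliberately well-separated panel (large hue/shape/rate gaps, low jitter).

    Used for segmentation fixtures and feature sanity checks where the classes
    should be far apart relative to within-class spread.
    """
    return [
        AccessionSpec("easy-a", linear_schedule(3, 0.6, 18), 4.6, 1.6, hue_center=70.0, hue_jitter=2.0),
        AccessionSpec("easy-b", linear_schedule(2, 0.3, 10), 2.4, 3.4, hue_center=95.0, hue_jitter=2.0),
        AccessionSpec("easy-c", linear_schedule(4, 0.8, 22), 3.6, 2.2, hue_center=120.0, hue_jitter=2.0,
                      rotation_phyllotaxy=99.5),
        AccessionSpec("easy-d", linear_schedule(2, 0.45, 14), 5.2, 2.8, hue_center=140.0, hue_jitter=2.0,
                      rotation_phyllotaxy=77.0),
    ]


# ---------------------------------------------------------------------------
# rendering

_SOIL_BASE = np.array([112.0, 84.0, 58.0])
_MAX_LEAVES = 64
_RENDER_SALT = 0x5EED


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    """Single HSV (h in degrees) to RGB in [0, 255]."""
    h = (h % 360.0) / 60.0
    i = int(h) % 6
    f = h - int(h)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb) * 255.0


def _plant_randomness(seed: int, canvas_size: int) -> dict:
    """Per-plant static nuisance draws; shared by every day of one plant."""
    rng = np.random.default_rng([_RENDER_SALT, int(seed)])
    low = gaussian_filter(rng.normal(0.0, 1.0, (canvas_size, canvas_size)),
                          sigma=max(canvas_size / 24.0, 2.0))
    low = low / (np.abs(low).max() + 1e-9)
    speckle = rng.normal(0.0, 6.0, (canvas_size, canvas_size))
    return {
        "hue_offset": rng.normal(),
        "base_rot": rng.uniform(0.0, 360.0),
        "leaf_jitter": rng.normal(0.0, 9.0, _MAX_LEAVES),
        "leaf_hue": rng.normal(0.0, 3.0, _MAX_LEAVES),
        "leaf_val": rng.uniform(-0.05, 0.05, _MAX_LEAVES),
        "bg_low": low,
        "bg_speckle": speckle,
        "pix_noise": rng.normal(0.0, 4.0, (canvas_size, canvas_size)),
        # residual colour-calibration error: per-plant white-balance gains
        "wb_gain": np.clip(rng.normal(1.0, 0.05, 3), 0.85, 1.15),
    }


def _leaf_appear_days(spec: AccessionSpec, n_leaves: int) -> np.ndarray:
    """Day (since germination) on which each leaf index first exists."""
    sched = spec.leaf_add_schedule
    appear = np.zeros(n_leaves, dtype=int)
    for k in range(n_leaves):
        for d, c in enumerate(sched):
            if c >= k + 1:
                appear[k] = d
                break
    return appear


def render_frame(
    spec: AccessionSpec,
    day: int,
    canvas_size: int = REFERENCE_CANVAS,
    seed: int = 0,
    germination_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one top-view frame and its ground-truth mask.

    Returns ``(rgb, mask)`` with ``rgb`` uint8 of shape (H, W, 3) and ``mask``
    boolean.  Deterministic for fixed ``(spec, day, canvas_size, seed)``.
    Besides the rosette geometry, the frame carries imaging nuisance that
    emulates residual colour-calibration error: a per-plant white-balance
    gain (s.d. 5% per channel) and a per-day exposure flicker (s.d. 3%).

    Raises ``ValueError`` if the canvas is too small to hold a plant.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    if canvas_size < 64:
        raise ValueError("canvas_size must be >= 64 to hold a rosette")

    scale = canvas_size / REFERENCE_CANVAS
    rand = _plant_randomness(seed, canvas_size)

    img = (_SOIL_BASE[None, None, :]
           + 18.0 * rand["bg_low"][:, :, None] * np.array([1.0, 0.85, 0.7])[None, None, :]
           + rand["bg_speckle"][:, :, None])
    mask = np.zeros((canvas_size, canvas_size), dtype=bool)

    eff_day = day - germination_offset
    n_leaves = min(spec.leaf_count(eff_day), _MAX_LEAVES)
    if n_leaves > 0:
        appear = _leaf_appear_days(spec, n_leaves)
        center = canvas_size / 2.0
        max_len = spec.max_leaf_len_frac * canvas_size
        hue0 = spec.hue_center + rand["hue_offset"] * spec.hue_jitter
        for k in range(n_leaves):
            age = eff_day - appear[k]
            length = min((3.0 + spec.expansion_rate * age) * scale, max_len)
            width = max(length / spec.leaf_aspect, 1.2)
            ang = np.deg2rad(rand["base_rot"] + k * spec.rotation_phyllotaxy
                             + rand["leaf_jitter"][k])
            r0 = center - np.sin(ang) * length / 2.0
            c0 = center + np.cos(ang) * length / 2.0
            rr, cc = draw_ellipse(r0, c0, width / 2.0, length / 2.0,
                                  shape=(canvas_size, canvas_size), rotation=ang)
            color = _hsv_to_rgb(hue0 + rand["leaf_hue"][k], 0.62,
                                0.47 + rand["leaf_val"][k])
            img[rr, cc] = color[None, :]
            mask[rr, cc] = True
        # per-pixel brightness noise on leaves so they are not flat
        img[mask] += rand["pix_noise"][mask][:, None]

    # imaging nuisance: leaf borders fade into the soil (optical blur),
    # per-plant white balance, per-day exposure flicker
    img = gaussian_filter(img, sigma=(0.8 * canvas_size / 128.0,) * 2 + (0.0,))
    day_rng = np.random.default_rng([_RENDER_SALT, int(seed), int(day) + 1])
    exposure = float(np.clip(day_rng.normal(1.0, 0.03), 0.9, 1.1))
    img = img * (rand["wb_gain"][None, None, :] * exposure)

    return np.clip(img, 0, 255).astype(np.uint8), mask


# ---------------------------------------------------------------------------
# dataset generation

def _plant_seed(seed: int, genotype: int, replicate: int) -> int:
    return int((seed * 1_000_003 + genotype * 10_007 + replicate * 101 + 17) % (2**31 - 1))


def generate_sequences(
    panel: Sequence[AccessionSpec],
    n_plants_per_class: int,
    n_days: int = 22,
    canvas_size: int = REFERENCE_CANVAS,
    seed: int = 0,
    with_masks: bool = True,
) -> list[PlantSequence]:
    """Generate in-memory sequences: one plant per (accession, replicate).

    Each plant draws a germination offset uniform on {0,1,2,3} days and a
    mild multiplicative expansion-rate jitter (s.d. 6%), so replicates of one
    accession differ while the accession's dynamics remain the signal.
    """
    if n_plants_per_class < 1:
        raise ValueError("n_plants_per_class must be >= 1")
    sequences: list[PlantSequence] = []
    for g, spec in enumerate(panel):
        for p in range(n_plants_per_class):
            pseed = _plant_seed(seed, g, p)
            prng = np.random.default_rng([0xB10, pseed])
            offset = int(prng.integers(0, 4))
            rate_jit = float(np.clip(prng.normal(1.0, 0.06), 0.8, 1.2))
            spec_p = dataclasses.replace(spec, expansion_rate=spec.expansion_rate * rate_jit)
            frames, masks = [], []
            for day in range(n_days):
                rgb, m = render_frame(spec_p, day, canvas_size, seed=pseed,
                                      germination_offset=offset)
                frames.append(rgb)
                masks.append(m)
            sequences.append(PlantSequence(
                plant_id=f"{spec.name}_{p:03d}",
                genotype=g,
                frames=frames,
                day_index=list(range(n_days)),
                truth_masks=masks if with_masks else None,
                genotype_name=spec.name,
            ))
    return sequences


def generate_dataset(
    panel: Sequence[AccessionSpec],
    out_dir: str | Path,
    n_plants_per_class: int,
    n_days: int = 22,
    canvas_size: int = REFERENCE_CANVAS,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a dataset to disk (PNG frames + masks) and return the manifest.

    Layout: ``<out>/<plant_id>/frame_DD.png`` and ``mask_DD.png``; manifest at
    ``<out>/manifest.csv`` with columns plant_id, genotype_name,
    genotype_index, day, frame_path, mask_path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in generate_sequences(panel, n_plants_per_class, n_days, canvas_size, seed):
        pdir = out / seq.plant_id
        pdir.mkdir(exist_ok=True)
        for day, frame, m in zip(seq.day_index, seq.frames, seq.truth_masks):
            fpath = pdir / f"frame_{day:02d}.png"
            mpath = pdir / f"mask_{day:02d}.png"
            iio.imwrite(fpath, frame)
            iio.imwrite(mpath, (m.astype(np.uint8) * 255))
            rows.append({
                "plant_id": seq.plant_id,
                "genotype_name": seq.genotype_name,
                "genotype_index": seq.genotype,
                "day": day,
                "frame_path": str(fpath.relative_to(out)),
                "mask_path": str(mpath.relative_to(out)),
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[PlantSequence]:
    """Load sequences written by :func:`generate_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    sequences = []
    for pid, grp in manifest.groupby("plant_id", sort=True):
        grp = grp.sort_values("day")
        frames = [iio.imread(root / p) for p in grp["frame_path"]]
        masks = [iio.imread(root / p) > 127 for p in grp["mask_path"]]
        sequences.append(PlantSequence(
            plant_id=str(pid),
            genotype=int(grp["genotype_index"].iloc[0]),
            frames=frames,
            day_index=[int(d) for d in grp["day"]],
            truth_masks=masks,
            genotype_name=str(grp["genotype_name"].iloc[0]),
        ))
    return sequences


def class_separation_ratio(features: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-class centroid distance over mean within-class spread.

    Features are standardised per dimension first.  The within-class spread is
    the r.m.s. distance of samples to their own class centroid, averaged over
    classes; the numerator is the smallest pairwise centroid distance.  Values
    above ~2 mean every class pair is well separated relative to scatter.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    classes = np.unique(y)
    cents = np.stack([X[y == c].mean(axis=0) for c in classes])
    within = float(np.mean([
        np.sqrt(np.mean(np.sum((X[y == c] - cents[i]) ** 2, axis=1)))
        for i, c in enumerate(classes)
    ]))
    d = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
    between = float(d[np.triu_indices(len(classes), 1)].min())
    return between / max(within, 1e-12)
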