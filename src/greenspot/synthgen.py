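"""Seeded synthetic plant imagery and field scenarios.

The generator produces parametric procedural morphotypes, not renderings of
real species: a compact rosette ("cabbage", overlapping elliptical lobes
around a filled centre), a thin pinnate brancher ("descurainia-like"), a
prostrate spreading mat ("portulaca-like") and a sparse upright brancher
("galinsoga-like"). The goal is the statistical structure the shape
descriptors exploit -- compact near-circular mass versus dispersed thin
branches -- over a textured brownish soil background whose excess-green
response is non-positive by construction.

Every stochastic choice derives from a master seed through per-object
seed sequences, so outputs are byte-identical for identical (config, seed)
and any single object can be regenerated without the rest.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk, ellipse, line

from .spray_sim import MM_PER_PX, FieldScenario, Plant

__all__ = [
    "SPECIES",
    "PlantSpec",
    "GeneratorConfig",
    "rng_for",
    "gen_cabbage",
    "gen_weed",
    "gen_plant",
    "gen_field_image",
    "gen_scenario",
    "gen_dataset",
]

SPECIES = ("cabbage", "portulaca-like", "descurainia-like", "galinsoga-like")

#: typical canopy extent per morphotype, mm (cabbage per the field mean)
DEFAULT_SIZE_MM = {
    "cabbage": 160.3,
    "portulaca-like": 150.0,
    "descurainia-like": 180.0,
    "galinsoga-like": 140.0,
}

_PLANT_GREEN = np.array([45, 135, 55], dtype=float)
_SOIL_BASE = np.array([120, 85, 60], dtype=float)
_HIGHLIGHT = np.array([232, 236, 226], dtype=float)


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Independent RNG stream derived from the master seed by stable hashing."""
    ints = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *ints]))


@dataclass
class PlantSpec:
    species: str = "cabbage"
    size_mm: float | None = None          # canopy extent; species default if None
    n_lobes: int | None = None            # rosette lobes / weed branches
    orientation: float = 0.0              # radians
    damage_frac: float = 0.0              # fraction of boundary bitten away
    highlight_frac: float = 0.0           # fraction of area washed out

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.size_mm is None:
            self.size_mm = DEFAULT_SIZE_MM[self.species]
        if self.size_mm <= 0:
            raise ValueError("size must be positive")
        for name in ("damage_frac", "highlight_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    width: int = 640
    height: int = 480
    mm_per_px: float = MM_PER_PX
    illumination: str = "uniform"         # "uniform" (active light) | "gradient"
    soil_darkness: float = 1.0            # surface-moisture proxy, multiplies soil
    soil_noise: float = 0.16              # texture amplitude, fraction of base
    allow_overlap: bool = False
    seed: int = 0


def _unit(angle: float) -> np.ndarray:
    return np.array([np.sin(angle), np.cos(angle)])  # (row, col) steps


def _thick_line(mask: np.ndarray, r0: int, c0: int, r1: int, c1: int,
                width: int) -> None:
    rr, cc = line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    stroke = np.zeros_like(mask)
    stroke[rr[keep], cc[keep]] = True
    if width > 1:
        stroke = ndi.binary_dilation(stroke, iterations=width // 2)
    mask |= stroke


def _paint(mask: np.ndarray, rng: np.random.Generator,
           spec: PlantSpec) -> np.ndarray:
    """Green fill with mild per-pixel shading; optional washed-out highlight."""
    h, w = mask.shape
    rgb = np.zeros((h, w, 3), dtype=float)
    shade = 1.0 + 0.10 * ndi.gaussian_filter(rng.standard_normal((h, w)), 2.0)
    for ch in range(3):
        rgb[:, :, ch] = _PLANT_GREEN[ch] * shade
    if spec.highlight_frac > 0 and mask.any():
        pix = np.argwhere(mask)
        n_spots = max(1, int(3 * spec.highlight_frac))
        radius = max(2, int(np.sqrt(spec.highlight_frac * mask.sum() / n_spots / np.pi)))
        for _ in range(n_spots):
            r0, c0 = pix[rng.integers(len(pix))]
            rr, cc = disk((r0, c0), radius, shape=mask.shape)
            rgb[rr, cc] = _HIGHLIGHT
    rgb[~mask] = 0.0
    return rgb


def _bite_damage(mask: np.ndarray, rng: np.random.Generator,
                 frac: float, size_px: float) -> None:
    if frac <= 0:
        return
    boundary = mask & ~ndi.binary_erosion(mask, iterations=2)
    pix = np.argwhere(boundary)
    if len(pix) == 0:
        return
    for _ in range(max(1, int(6 * frac))):
        r0, c0 = pix[rng.integers(len(pix))]
        rr, cc = disk((r0, c0), max(2, 0.12 * size_px), shape=mask.shape)
        mask[rr, cc] = False


def gen_cabbage(spec: PlantSpec, rng: np.random.Generator,
                mm_per_px: float = MM_PER_PX) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rosette: 6-12 overlapping elliptical lobes around a filled centre.

    Returns (mask, RGB patch, ground truth). The blob is compact and
    near-circular; its skeleton carries several central branch points and its
    ring profile decays outward.
    """
    size_px = spec.size_mm / mm_per_px
    R0 = size_px / 2.0
    S = int(2.2 * R0) + 9
    ctr = S / 2.0
    mask = np.zeros((S, S), dtype=bool)
    n = spec.n_lobes if spec.n_lobes is not None else int(rng.integers(6, 13))
    base = spec.orientation + rng.uniform(0, 2 * np.pi)
    for k in range(n):
        ang = base + 2 * np.pi * k / n + rng.normal(0, 0.10)
        d = _unit(ang)
        cy = ctr + 0.45 * R0 * d[0] * rng.uniform(0.9, 1.05)
        cx = ctr + 0.45 * R0 * d[1] * rng.uniform(0.9, 1.05)
        rr, cc = ellipse(cy, cx,
                         0.55 * R0 * rng.uniform(0.9, 1.1),
                         0.30 * R0 * rng.uniform(0.85, 1.1),
                         shape=mask.shape, rotation=-ang)
        mask[rr, cc] = True
    rr, cc = disk((ctr, ctr), 0.35 * R0, shape=mask.shape)
    mask[rr, cc] = True
    # soil gaps between overlapping leaves: interior holes whose skeleton
    # loops carry the rosette's many distributed intersection points
    n_holes = int(rng.integers(10, 17))
    for _ in range(n_holes):
        a = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.25, 0.62) * R0
        rr, cc = disk((ctr + rad * np.sin(a), ctr + rad * np.cos(a)),
                      rng.uniform(3.5, 5.2), shape=mask.shape)
        mask[rr, cc] = False
    _bite_damage(mask, rng, spec.damage_frac, size_px)
    rgb = _paint(mask, rng, spec)
    truth = {"species": spec.species, "size_mm": spec.size_mm, "area_px": int(mask.sum())}
    return mask, rgb.astype(np.uint8), truth


def _gen_pinnate(spec: PlantSpec, rng: np.random.Generator, mm_per_px: float
                 ) -> np.ndarray:
    """Thin central stem with paired thin side branches (low circularity)."""
    size_px = spec.size_mm / mm_per_px
    S = int(1.3 * size_px) + 9
    ctr = S // 2
    mask = np.zeros((S, S), dtype=bool)
    ang = spec.orientation + rng.uniform(0, 2 * np.pi)
    d = _unit(ang)
    half = size_px / 2.0
    p0 = np.array([ctr, ctr]) - d * half
    p1 = np.array([ctr, ctr]) + d * half
    _thick_line(mask, *np.rint(p0).astype(int), *np.rint(p1).astype(int), width=5)
    n_pairs = spec.n_lobes if spec.n_lobes is not None else int(rng.integers(5, 9))
    for i in range(n_pairs):
        frac = 0.12 + 0.8 * i / max(n_pairs - 1, 1)
        root = p0 + d * (frac * size_px)
        blen = 0.40 * size_px * (1.0 - 0.6 * frac) * rng.uniform(0.8, 1.2)
        for side in (+1, -1):
            bang = ang + side * rng.uniform(0.75, 1.05)
            tip = root + _unit(bang) * blen
            _thick_line(mask, *np.rint(root).astype(int), *np.rint(tip).astype(int),
                        width=5)
            rr, cc = disk(tuple(np.rint(tip).astype(int)), 3, shape=mask.shape)
            mask[rr, cc] = True
    return mask


def _gen_prostrate(spec: PlantSpec, rng: np.random.Generator, mm_per_px: float
                   ) -> np.ndarray:
    """Crawling stems with small oval leaves scattered along them."""
    size_px = spec.size_mm / mm_per_px
    S = int(1.3 * size_px) + 9
    ctr = float(S // 2)
    mask = np.zeros((S, S), dtype=bool)
    n_stems = spec.n_lobes if spec.n_lobes is not None else int(rng.integers(4, 6))
    for s in range(n_stems):
        ang = spec.orientation + 2 * np.pi * s / n_stems + rng.normal(0, 0.3)
        pos = np.array([ctr, ctr])
        step = size_px / 12.0
        for _ in range(5):
            ang += rng.normal(0, 0.35)
            nxt = pos + _unit(ang) * step
            nxt = np.clip(nxt, 4, S - 5)
            _thick_line(mask, *np.rint(pos).astype(int), *np.rint(nxt).astype(int),
                        width=5)
            # fleshy leaves sit on the stem path, so the mat reads as dense
            # lobed strands rather than thin branches
            ly, lx = np.rint(nxt).astype(int)
            rr, cc = ellipse(ly, lx, 0.085 * size_px, 0.055 * size_px,
                             shape=mask.shape, rotation=float(ang))
            mask[rr, cc] = True
            pos = nxt
    return mask


def _gen_upright(spec: PlantSpec, rng: np.random.Generator, mm_per_px: float
                 ) -> np.ndarray:
    """Few diverging upright branches with small round leaves near the tips."""
    size_px = spec.size_mm / mm_per_px
    S = int(1.3 * size_px) + 9
    ctr = float(S // 2)
    mask = np.zeros((S, S), dtype=bool)
    base = np.array([ctr, ctr])
    n_branches = spec.n_lobes if spec.n_lobes is not None else int(rng.integers(2, 5))
    up = spec.orientation + rng.uniform(0, 2 * np.pi)
    for b in range(n_branches):
        bang = up + (b - (n_branches - 1) / 2.0) * 0.55 + rng.normal(0, 0.1)
        blen = size_px * rng.uniform(0.45, 0.62)
        tip = base + _unit(bang) * blen
        tip = np.clip(tip, 4, S - 5)
        _thick_line(mask, *np.rint(base).astype(int), *np.rint(tip).astype(int),
                    width=5)
        for frac in (0.6, 1.0):
            leaf = base + (tip - base) * frac
            rr, cc = disk(tuple(np.rint(leaf).astype(int)),
                          max(3, 0.05 * size_px), shape=mask.shape)
            mask[rr, cc] = True
    return mask


_WEED_BUILDERS = {
    "descurainia-like": _gen_pinnate,
    "portulaca-like": _gen_prostrate,
    "galinsoga-like": _gen_upright,
}


def gen_weed(spec: PlantSpec, rng: np.random.Generator,
             mm_per_px: float = MM_PER_PX) -> tuple[np.ndarray, np.ndarray, dict]:
    """One of the three weed morphotypes with seeded shape jitter."""
    if spec.species not in _WEED_BUILDERS:
        raise ValueError(f"not a weed morphotype: {spec.species!r}")
    mask = _WEED_BUILDERS[spec.species](spec, rng, mm_per_px)
    _bite_damage(mask, rng, spec.damage_frac, spec.size_mm / mm_per_px)
    rgb = _paint(mask, rng, spec)
    truth = {"species": spec.species, "size_mm": spec.size_mm, "area_px": int(mask.sum())}
    return mask, rgb.astype(np.uint8), truth


def gen_plant(spec: PlantSpec, rng: np.random.Generator,
              mm_per_px: float = MM_PER_PX) -> tuple[np.ndarray, np.ndarray, dict]:
    if spec.species == "cabbage":
        return gen_cabbage(spec, rng, mm_per_px)
    return gen_weed(spec, rng, mm_per_px)


def _soil(h: int, w: int, cfg: GeneratorConfig, rng: np.random.Generator
          ) -> np.ndarray:
    """Brownish value-noise texture; luminance-only, so its ExG stays <= 0."""
    fine = ndi.gaussian_filter(rng.standard_normal((h, w)), 2.0)
    coarse = ndi.gaussian_filter(rng.standard_normal((h, w)), 12.0)
    tex = fine / max(fine.std(), 1e-9) * 0.5 + coarse / max(coarse.std(), 1e-9)
    factor = 1.0 + cfg.soil_noise * tex / max(tex.std(), 1e-9)
    factor = np.clip(factor, 0.4, 1.6) * cfg.soil_darkness
    return np.clip(_SOIL_BASE[None, None, :] * factor[:, :, None], 0, 255)


def _illumination(h: int, w: int, cfg: GeneratorConfig) -> np.ndarray:
    if cfg.illumination == "uniform":
        return np.ones((h, w))
    if cfg.illumination == "gradient":
        return np.linspace(0.72, 1.12, h)[:, None] * np.ones((1, w))
    raise ValueError(f"unknown illumination mode {cfg.illumination!r}")


def gen_field_image(layout: list[tuple[PlantSpec, tuple[int, int]]],
                    cfg: GeneratorConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Composite plant patches over textured soil; truth is exact by construction.

    ``layout`` holds (spec, (row, col)) with positions at patch centres.
    Returns the RGB image and a ground-truth table (species, bbox, centroid).
    """
    h, w = cfg.height, cfg.width
    img = _soil(h, w, cfg, rng_for(cfg.seed, "soil"))
    records = []
    occupied = np.zeros((h, w), dtype=bool)
    for i, (spec, (py, px)) in enumerate(layout):
        rng = rng_for(cfg.seed, "plant", i)
        mask, rgb, truth = gen_plant(spec, rng, cfg.mm_per_px)
        ph, pw = mask.shape
        top, left = py - ph // 2, px - pw // 2
        if top < 0 or left < 0 or top + ph > h or left + pw > w:
            raise ValueError(f"plant {i} does not fit inside the frame")
        region = occupied[top:top + ph, left:left + pw]
        overlaps = bool((region & mask).any())
        if overlaps and not cfg.allow_overlap:
            raise ValueError(f"plant {i} overlaps a previous plant")
        img[top:top + ph, left:left + pw][mask] = rgb[mask]
        region |= mask
        rows, cols = np.nonzero(mask)
        records.append({
            "plant_id": i, "species": spec.species,
            "centroid_row": float(rows.mean()) + top,
            "centroid_col": float(cols.mean()) + left,
            "top": top + rows.min(), "left": left + cols.min(),
            "bottom": top + rows.max() + 1, "right": left + cols.max() + 1,
            "area_px": int(mask.sum()), "overlaps": overlaps,
        })
    img = img * _illumination(h, w, cfg)[:, :, None]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), pd.DataFrame(records)


def gen_scenario(ridge_length_m: float = 70.0, spacing_mm: float = 400.0,
                 void_rate: float = 0.0, species_mix: dict[str, float] | None = None,
                 seed: int = 0, length_mean_mm: float = 160.3,
                 length_sd_mm: float = 25.0) -> FieldScenario:
    """Plant slots every ``spacing_mm`` along a ridge; each empty with P(void).

    Plant lengths are drawn from a clipped normal around the field mean
    canopy length (160.3 mm). Species default to all-cabbage.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if not 0.0 <= void_rate < 1.0:
        raise ValueError("void rate must lie in [0, 1)")
    rng = rng_for(seed, "scenario")
    mix = species_mix or {"cabbage": 1.0}
    names = sorted(mix)
    probs = np.array([mix[k] for k in names], dtype=float)
    probs /= probs.sum()
    n_slots = int(ridge_length_m * 1000.0 / spacing_mm)
    plants = []
    for slot in range(n_slots):
        occupied = rng.random() >= void_rate
        species = names[rng.choice(len(names), p=probs)]
        length = float(np.clip(rng.normal(length_mean_mm, length_sd_mm),
                               40.0, 0.9 * spacing_mm))
        if not occupied:
            continue
        center = slot * spacing_mm + spacing_mm / 2.0
        plants.append(Plant(position_mm=center - length / 2.0,
                            length_mm=length, species=species))
    return FieldScenario(plants=plants, ridge_length_m=ridge_length_m,
                         spacing_mm=spacing_mm, void_rate=void_rate)


@dataclass
class DatasetRecord:
    image_id: str
    species: str
    image: np.ndarray = field(repr=False)
    truth: dict = field(repr=False)


def gen_dataset(n_per_class: int, cfg: GeneratorConfig | None = None,
                seed: int = 0, out_dir=None
                ) -> tuple[list[DatasetRecord], pd.DataFrame]:
    """Balanced 4-class single-plant image set with a manifest.

    Each image holds one plant centred (with jitter) on a soil patch sized to
    the morphotype. Per-image RNG streams derive from (seed, species, index),
    so the corpus is deterministic and individual images re-generate alone.
    With ``out_dir`` set, images are written as PNG next to a manifest CSV.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    cfg = cfg or GeneratorConfig()
    records: list[DatasetRecord] = []
    rows = []
    for species in SPECIES:
        for j in range(n_per_class):
            rng = rng_for(seed, "dataset", species, j)
            size = float(np.clip(rng.normal(DEFAULT_SIZE_MM[species],
                                            0.12 * DEFAULT_SIZE_MM[species]),
                                 60.0, 280.0))
            spec = PlantSpec(species=species, size_mm=size,
                             orientation=float(rng.uniform(0, 2 * np.pi)),
                             highlight_frac=float(rng.choice([0.0, 0.05], p=[0.8, 0.2])),
                             damage_frac=float(rng.choice([0.0, 0.15], p=[0.85, 0.15])))
            mask, rgb, truth = gen_plant(spec, rng, cfg.mm_per_px)
            ph, pw = mask.shape
            margin = 14
            h, w = ph + 2 * margin, pw + 2 * margin
            img = _soil(h, w, cfg, rng)
            jy, jx = rng.integers(-margin // 2, margin // 2 + 1, 2)
            top, left = margin + jy, margin + jx
            img[top:top + ph, left:left + pw][mask] = rgb[mask]
            img = img * _illumination(h, w, cfg)[:, :, None]
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            image_id = f"{species}_{j:04d}"
            records.append(DatasetRecord(image_id=image_id, species=species,
                                         image=img, truth=truth))
            rows.append({"image_id": image_id, "species": species,
                         "path": f"{image_id}.png" if out_dir else ""})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            Image.fromarray(rec.image).save(out / f"{rec.image_id}.png")
        manifest.to_csv(out / "manifest.csv", index=False)
    return records, manifest
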