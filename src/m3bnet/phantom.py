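"""Synthetic paired UWF-like / FFA-like fundus phantoms with exact vessel masks.

Real ultra-widefield photographs show thin, low-contrast vessels on a bright,
unevenly illuminated background, while the angiography counterpart shows the
same vasculature bright on a dark background.  The phantom reproduces exactly
those statistics — and nothing more — so that every downstream stage of the
pipeline (style transfer, multi-scale encoding, selective fusion, evaluation)
can be trained and tested without any data download:

* a recursive binary branching tree with angular jitter and per-generation
  width/length decay stands in for the vasculature; terminal generations
  thin down to 1–2 px to exercise the fine-vessel failure mode;
* the binary rasterization of that tree is the ground-truth mask shared by
  both rendered modalities, so the pair is pixel-aligned by construction;
* a sum of low-frequency cosine modes models uneven illumination, and
  additive Gaussian noise models sensor noise;
* a circular field-of-view mask is emitted as the valid-region mask.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

Point = tuple[float, float]


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings.  Intensities live in [0, 1]; widths in pixels."""

    canvas_size: int = 128
    n_trees: int = 2
    depth: int = 5
    width_root: float = 3.0
    width_decay: float = 0.8
    uwf_contrast: float = 0.15
    illum_amplitude: float = 0.15
    noise_sigma: float = 0.03
    ffa_contrast: float = 0.55
    background: float = 0.55
    ffa_background: float = 0.12
    branch_jitter_deg: float = 30.0
    length_decay: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.canvas_size < 64:
            raise ValueError("canvas_size must be >= 64")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.width_root <= 0:
            raise ValueError("width_root must be > 0")
        if not 0 < self.width_decay <= 1:
            raise ValueError("width_decay must lie in (0, 1]")
        for name in ("uwf_contrast", "illum_amplitude", "noise_sigma", "ffa_contrast"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.uwf_contrast >= self.ffa_contrast:
            raise ValueError("uwf_contrast must be < ffa_contrast (the angiogram is the high-contrast modality)")


@dataclass
class VesselTree:
    """Piecewise-linear branching tree.  Segments are (start, end, width)."""

    segments: list[tuple[Point, Point, float]]
    roots: list[Point]
    depth: int

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class SamplePair:
    """An aligned UWF/FFA phantom pair sharing one exact vessel mask."""

    uwf: np.ndarray
    mask: np.ndarray
    ffa: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {a.shape for a in (self.uwf, self.mask, self.ffa, self.valid_mask) if a is not None}
        if len(shapes) != 1:
            raise ValueError(f"all arrays of a SamplePair must share one shape, got {shapes}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _clip_point(p: np.ndarray, canvas: int) -> tuple[float, float]:
    return (float(np.clip(p[0], 0.0, canvas - 1.0)), float(np.clip(p[1], 0.0, canvas - 1.0)))


def generate_vessel_tree(params: PhantomParams, rng_seed: int) -> VesselTree:
    """Grow ``n_trees`` recursive binary trees rooted on the field-of-view rim.

    Deterministic for a fixed (params, rng_seed).  Each generation halves into
    two children with angular jitter up to ±branch_jitter_deg, width scaled by
    width_decay and length by length_decay; depth 1 yields unbranched trunks.
    """
    params.validate()
    rng = np.random.default_rng(rng_seed)
    c = params.canvas_size
    centre = np.array([c / 2.0, c / 2.0])
    fov_radius = 0.48 * c
    base_len = 0.30 * c
    jitter = np.deg2rad(params.branch_jitter_deg)

    segments: list[tuple[Point, Point, float]] = []
    roots: list[Point] = []

    def grow(start: np.ndarray, angle: float, width: float, length: float, gen: int) -> None:
        end = start + length * np.array([np.sin(angle), np.cos(angle)])
        p0, p1 = _clip_point(start, c), _clip_point(end, c)
        segments.append((p0, p1, width))
        if gen + 1 >= params.depth:
            return
        for sign in (-1.0, 1.0):
            child_angle = angle + sign * rng.uniform(0.2, 1.0) * jitter
            grow(np.asarray(p1), child_angle, width * params.width_decay,
                 length * params.length_decay, gen + 1)

    for _ in range(params.n_trees):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        root = centre + fov_radius * np.array([np.sin(theta), np.cos(theta)])
        root = np.asarray(_clip_point(root, c))
        roots.append((float(root[0]), float(root[1])))
        inward = np.arctan2(centre[0] - root[0], centre[1] - root[1])
        inward += rng.uniform(-0.3, 0.3)
        grow(root, inward, params.width_root, base_len, 0)

    return VesselTree(segments=segments, roots=roots, depth=params.depth)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_tree(tree: VesselTree, canvas_size: int) -> np.ndarray:
    """Binary rasterization: butt-capped thick lines, no anti-aliasing.

    A pixel (integer centre) belongs to a segment iff its projection onto the
    segment's axis falls within [0, L] and its perpendicular distance is at
    most width/2.  The result is the exact ground truth for both modalities.
    """
    mask = np.zeros((canvas_size, canvas_size), dtype=np.uint8)
    for (r0, c0), (r1, c1), w in tree.segments:
        half = w / 2.0
        dr, dc = r1 - r0, c1 - c0
        length = np.hypot(dr, dc)
        if length == 0:
            continue
        ur, uc = dr / length, dc / length
        rmin = max(int(np.floor(min(r0, r1) - half)), 0)
        rmax = min(int(np.ceil(max(r0, r1) + half)), canvas_size - 1)
        cmin = max(int(np.floor(min(c0, c1) - half)), 0)
        cmax = min(int(np.ceil(max(c0, c1) + half)), canvas_size - 1)
        if rmin > rmax or cmin > cmax:
            continue
        rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
        pr, pc = rr - r0, cc - c0
        t = pr * ur + pc * uc
        perp = np.abs(pr * uc - pc * ur)
        hit = (t >= 0.0) & (t <= length) & (perp <= half)
        mask[rmin:rmax + 1, cmin:cmax + 1][hit] = 1
    return mask


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _illumination_field(canvas: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field in [-amplitude, amplitude]: 2–4 cosine modes."""
    if amplitude == 0:
        return np.zeros((canvas, canvas))
    n_modes = int(rng.integers(2, 5))
    rr, cc = np.mgrid[0:canvas, 0:canvas] / canvas
    fld = np.zeros((canvas, canvas))
    for _ in range(n_modes):
        fr, fc = rng.uniform(0.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        fld += np.cos(2 * np.pi * (fr * rr + fc * cc) + phase)
    peak = np.abs(fld).max()
    return amplitude * fld / peak if peak > 0 else fld


def fov_mask(canvas_size: int, radius_fraction: float = 0.48) -> np.ndarray:
    rr, cc = np.mgrid[0:canvas_size, 0:canvas_size]
    centre = (canvas_size - 1) / 2.0
    return ((rr - centre) ** 2 + (cc - centre) ** 2 <= (radius_fraction * canvas_size) ** 2).astype(np.uint8)


def render_pair(mask: np.ndarray, params: PhantomParams, rng_seed: int) -> SamplePair:
    """Render the two modalities from one shared mask.

    UWF: bright background + low-frequency illumination − dark vessels + noise.
    FFA: dark background + bright vessels + noise.  Both clipped to [0, 1].
    """
    params.validate()
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    rng = np.random.default_rng(rng_seed)
    canvas = mask.shape[0]
    m = mask.astype(np.float64)

    illum = _illumination_field(canvas, params.illum_amplitude, rng)
    noise_uwf = rng.normal(0.0, params.noise_sigma, mask.shape) if params.noise_sigma else 0.0
    noise_ffa = rng.normal(0.0, params.noise_sigma, mask.shape) if params.noise_sigma else 0.0

    uwf = np.clip(params.background + illum - params.uwf_contrast * m + noise_uwf, 0.0, 1.0)
    ffa = np.clip(params.ffa_background + params.ffa_contrast * m + noise_ffa, 0.0, 1.0)
    return SamplePair(
        uwf=uwf.astype(np.float32),
        ffa=ffa.astype(np.float32),
        mask=mask.astype(np.uint8),
        valid_mask=fov_mask(canvas),
        meta={"seed": int(rng_seed), "params": dataclasses.asdict(params)},
    )


def generate_pair(params: PhantomParams, rng_seed: int) -> SamplePair:
    """Convenience: tree → mask → rendered pair, all from one seed."""
    tree = generate_vessel_tree(params, rng_seed)
    mask = rasterize_tree(tree, params.canvas_size)
    return render_pair(mask, params, rng_seed)


# ---------------------------------------------------------------------------
# dataset on disk
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("id", "uwf", "ffa", "mask", "valid_mask", "seed")


def _write_png(path: Path, array: np.ndarray) -> None:
    arr = np.round(np.clip(array, 0.0, 1.0) * 255.0).astype(np.uint8) if array.dtype != np.uint8 else array
    Image.fromarray(arr, mode="L").save(path)


def _pair_seed(root_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] % (2 ** 31))


def generate_dataset(n_pairs: int, params: PhantomParams, out_dir: str | Path, seed: int) -> Path:
    """Write ``n_pairs`` rendered pairs as 8-bit PNGs plus a CSV manifest.

    Fully reproducible: each pair's seed derives from (seed, index), and PNG
    encoding carries no timestamps, so regeneration is byte-identical.
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_pairs):
        ps = _pair_seed(seed, i)
        pair = generate_pair(params, ps)
        names = {k: f"{i:04d}_{k}.png" for k in ("uwf", "ffa", "mask", "valid_mask")}
        _write_png(out / names["uwf"], pair.uwf)
        _write_png(out / names["ffa"], pair.ffa)
        _write_png(out / names["mask"], pair.mask * 255)
        _write_png(out / names["valid_mask"], pair.valid_mask * 255)
        rows.append({"id": f"{i:04d}", **names, "seed": ps})
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    with open(out / "params.json", "w") as fh:
        json.dump({"params": dataclasses.asdict(params), "seed": seed, "n_pairs": n_pairs}, fh, indent=2)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[SamplePair]:
    """Read a manifest back into memory as float [0, 1] SamplePairs."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    pairs = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            def load(name, binary=False):
                if not row.get(name):
                    return None
                arr = np.asarray(Image.open(base / row[name]), dtype=np.float32) / 255.0
                return (arr > 0.5).astype(np.uint8) if binary else arr

            pairs.append(SamplePair(
                uwf=load("uwf"), ffa=load("ffa"),
                mask=load("mask", binary=True), valid_mask=load("valid_mask", binary=True),
                meta={"id": row["id"], "seed": int(row["seed"])},
            ))
    return pairs
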