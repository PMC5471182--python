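"""Synthetic datasets with the statistical structure the analysis assumes.

Generates a pure-birth phylogeny, a smooth habitat-colour gradient raster,
and a specimen table in which fur colour is the sum of a habitat effect, a
phylogenetically structured (Brownian) species effect, a latitudinal
gradient, a field/museum brightness offset and individual noise — so every
pipeline stage can be exercised, and parameter recovery tested, without the
museum photographs or satellite imagery of a real study.

Default condition (one seeded draw): 14 species on a Yule tree, about 460
specimens with per-species counts in the 5-120 range, roughly 20% field /
80% museum specimens spread over five museum collections, a positive
habitat effect, a negative latitude slope and a positive field brightness
offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from crypsis.colorimetry import total_reflectance
from crypsis.habitat import GeoTransform, HabitatRaster
from crypsis.phylo_eigen import PhyloTree, parse_newick, simulate_bm

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_yule_tree",
    "generate_raster",
    "simulate_dataset",
    "render_patch_images",
]

CHANNELS = ("red", "green", "blue")

# Balanced 14-taxon ultrametric reference phylogeny (depth 1): three
# quartets plus a cherry radiating from the root.  Used as the fixed tree
# for phylogenetic-signal calibration examples and tests: its even
# eigenvalue spectrum keeps sequential-R² curves close to the 1:1 Brownian
# line while retaining clear phylogenetic structure.
REFERENCE_TREE_NEWICK = (
    "(((A:0.45,B:0.45):0.35,(C:0.45,D:0.45):0.35):0.2,"
    "((E:0.45,F:0.45):0.35,(G:0.45,H:0.45):0.35):0.2,"
    "((I:0.45,J:0.45):0.35,(K:0.45,L:0.45):0.35):0.2,"
    "(M:0.8,N:0.8):0.2);"
)

# desert-substrate base tones on the 0-255 reflectance scale
_FUR_BASE = {"red": 150.0, "green": 125.0, "blue": 95.0}
_HAB_BASE = {"red": 140.0, "green": 120.0, "blue": 90.0}
_HAB_AMPLITUDE = {"red": 50.0, "green": 45.0, "blue": 35.0}

# linear local scaling: meters per degree of latitude
M_PER_DEG = 111_320.0


@dataclass
class SimConfig:
    """Generative parameters of the synthetic study.

    Units: colours on the 0-255 reflectance scale; b_hab is unitless
    (fur units per habitat unit); b_lat in reflectance units per degree of
    latitude; sigma2_phylo in squared reflectance units per unit of tree
    depth; the spatial domain is projected (meters), with latitude derived
    linearly from northing.
    """

    n_species: int = 14
    total_specimens: int = 460
    specimens_per_species: tuple[int, int] = (5, 120)
    birth_rate: float = 1.0
    sigma2_phylo: float = 25.0
    b_hab: float = 0.5
    b_lat: float = -3.0
    field_offset: float = 8.0
    field_fraction: float = 0.2
    n_collections: int = 5
    noise_sd: float = 6.0
    raster_shape: tuple[int, int] = (250, 250)
    pixel_size: float = 2000.0  # meters
    raster_noise_sd: float = 5.0
    gradient_direction_deg: float = 0.0
    # None: specimen locations drawn uniformly over the domain (species are
    # spatially exchangeable).  A float enables clustered species ranges:
    # per-species centers with Normal(range_sd) dispersal around them.
    range_sd: float | None = None
    lat0: float = 20.0  # latitude of the southern domain edge, degrees N
    lon0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be at least 4")
        for name in ("sigma2_phylo", "noise_sd", "raster_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticDataset:
    """A generated study: tree, specimen table, rasters and the truth."""

    tree: PhyloTree
    newick: str
    specimens: pd.DataFrame
    raster: HabitatRaster
    period_rasters: tuple[list[HabitatRaster], list[HabitatRaster]]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Emit tree.nwk, specimens.csv, truth.json and the raster files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(self.newick + "\n")
        self.specimens.to_csv(outdir / "specimens.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))
        self.raster.write(outdir / "habitat_mean.tif")
        for label, group in zip(("period1", "period2"), self.period_rasters):
            for i, r in enumerate(group):
                r.write(outdir / f"habitat_{label}_{i}.tif")


def generate_yule_tree(
    n: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> PhyloTree:
    """Pure-birth (Yule) tree with exactly ``n`` tips.

    Lineages split after exponential waiting times with total rate
    k * birth_rate; after the n-th lineage appears the process runs for one
    further Exp(n * birth_rate) interval so every pendant edge has positive
    length.
    """
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    next_id = [0]

    def new_leaf() -> dict:
        next_id[0] += 1
        return {"children": None, "length": 0.0, "label": f"sp{next_id[0]:02d}"}

    root = {"children": [new_leaf(), new_leaf()], "length": None, "label": None}
    active = list(root["children"])
    while len(active) < n:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for leaf in active:
            leaf["length"] += wait
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent["children"] = [new_leaf(), new_leaf()]
        active.extend(parent["children"])
    tail = rng.exponential(1.0 / (birth_rate * n))
    for leaf in active:
        leaf["length"] += tail

    # labels were assigned in creation order; relabel tips left-to-right
    labels = iter(f"sp{i + 1:02d}" for i in range(n))

    def newick(node: dict) -> str:
        if node["children"] is None:
            return f"{next(labels)}:{node['length']:.10g}"
        inner = ",".join(newick(c) for c in node["children"])
        length = "" if node["length"] is None else f":{node['length']:.10g}"
        return f"({inner}){length}"

    return parse_newick(newick(root) + ";")


def _gradient_field(
    shape: tuple[int, int], direction_deg: float
) -> np.ndarray:
    """Unit-range linear gradient across the grid in a given direction."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    theta = np.radians(direction_deg)
    proj = cols * np.cos(theta) + rows * np.sin(theta)
    span = proj.max() - proj.min()
    return (proj - proj.min()) / (span if span else 1.0)


def generate_raster(
    shape: tuple[int, int] = (250, 250),
    pixel_size: float = 2000.0,
    direction_deg: float = 30.0,
    amplitude: dict[str, float] | None = None,
    base: dict[str, float] | None = None,
    noise_sd: float = 5.0,
    seed: int | np.random.Generator = 0,
    n_periods: tuple[int, int] = (0, 0),
    period_shift: float = 0.0,
    period_noise_sd: float = 0.0,
) -> tuple[HabitatRaster, tuple[list[HabitatRaster], list[HabitatRaster]]]:
    """Smooth linear-gradient RGB raster plus optional two period stacks.

    All three bands share one gradient field (habitat colours are strongly
    inter-correlated in reflectance data), scaled by a per-band amplitude
    over a per-band base tone, plus white noise.  When ``n_periods`` is
    nonzero, two stacks of per-period layers are also produced around the
    mean raster: the second stack offset by ``period_shift`` per channel,
    each layer with extra noise ``period_noise_sd`` — the between/within
    structure a period-split repeatability (ICC) design measures.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amplitude = amplitude or dict(_HAB_AMPLITUDE)
    base = base or dict(_HAB_BASE)
    g = _gradient_field(shape, direction_deg)
    transform = GeoTransform(0.0, shape[0] * pixel_size, pixel_size, pixel_size)
    bands = {
        c: base[c] + amplitude[c] * g + rng.normal(0.0, noise_sd, shape)
        for c in CHANNELS
    }
    mean_raster = HabitatRaster(bands["red"], bands["green"], bands["blue"], transform)

    def make_stack(count: int, shift: float) -> list[HabitatRaster]:
        stack = []
        for _ in range(count):
            layers = [
                bands[c] + shift + rng.normal(0.0, period_noise_sd, shape)
                for c in CHANNELS
            ]
            stack.append(HabitatRaster(*layers, transform=transform))
        return stack

    periods = (make_stack(n_periods[0], 0.0), make_stack(n_periods[1], period_shift))
    return mean_raster, periods


def _allocate_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.specimens_per_species
    raw = rng.integers(lo, hi + 1, size=cfg.n_species).astype(float)
    counts = np.maximum(np.round(raw / raw.sum() * cfg.total_specimens), 2).astype(int)
    # nudge to the exact total, never below 2 per species
    while counts.sum() != cfg.total_specimens:
        j = int(rng.integers(cfg.n_species))
        if counts.sum() > cfg.total_specimens and counts[j] > 2:
            counts[j] -= 1
        elif counts.sum() < cfg.total_specimens:
            counts[j] += 1
    return counts


def simulate_dataset(cfg: SimConfig | None = None) -> SyntheticDataset:
    """Draw one synthetic study under the generative model.

    Per species: a Brownian-motion effect on the tree and a range center in
    the spatial domain.  Per specimen: a location around its species'
    center, habitat colour read from the gradient raster at that location,
    and fur colour

        fur_c = mu_c + b_hab (hab_c - mean hab_c) + b_lat (lat - mean lat)
                + field_offset 1[field] + BM_species + Normal(0, noise_sd),

    truncated to [0, 255] (a warning reports truncation affecting > 5% of
    values).  Origin labels are ~20% field / 80% museum across
    ``n_collections`` museum collections.
    """
    import warnings

    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    tree = generate_yule_tree(cfg.n_species, cfg.birth_rate, rng)
    species_names = tree.taxa

    # gradient runs east-west by default, perpendicular to the latitudinal
    # brightness gradient, so the two effects stay identifiable
    raster, periods = generate_raster(
        shape=cfg.raster_shape,
        pixel_size=cfg.pixel_size,
        direction_deg=cfg.gradient_direction_deg,
        noise_sd=cfg.raster_noise_sd,
        seed=rng,
        n_periods=(3, 3),
        period_shift=2.0,
        period_noise_sd=3.0,
    )

    bm = {
        c: simulate_bm(tree, cfg.sigma2_phylo, 0.0, rng)
        if cfg.sigma2_phylo > 0
        else {s: 0.0 for s in species_names}
        for c in CHANNELS
    }

    counts = _allocate_counts(cfg, rng)
    height = cfg.raster_shape[0] * cfg.pixel_size
    width = cfg.raster_shape[1] * cfg.pixel_size
    if cfg.range_sd is not None:
        centers_x = rng.uniform(0.1 * width, 0.9 * width, cfg.n_species)
        centers_y = rng.uniform(0.1 * height, 0.9 * height, cfg.n_species)

    rows: list[dict] = []
    for si, (sp, n_sp) in enumerate(zip(species_names, counts)):
        if cfg.range_sd is None:
            x = rng.uniform(0.0, width - 1.0, n_sp)
            y = rng.uniform(0.0, height - 1.0, n_sp)
        else:
            x = np.clip(
                rng.normal(centers_x[si], cfg.range_sd, n_sp), 0.0, width - 1.0
            )
            y = np.clip(
                rng.normal(centers_y[si], cfg.range_sd, n_sp), 0.0, height - 1.0
            )
        col = np.clip((x / cfg.pixel_size).astype(int), 0, cfg.raster_shape[1] - 1)
        row = np.clip(
            ((height - y) / cfg.pixel_size).astype(int), 0, cfg.raster_shape[0] - 1
        )
        for i in range(n_sp):
            rec = {
                "species": sp,
                "x": x[i],
                "y": y[i],
                "latitude": cfg.lat0 + y[i] / M_PER_DEG,
                "longitude": cfg.lon0 + x[i] / M_PER_DEG,
            }
            for c in CHANNELS:
                rec[f"habitat_{c}"] = float(getattr(raster, c)[row[i], col[i]])
            rows.append(rec)
    df = pd.DataFrame(rows)
    n = len(df)
    df.insert(0, "id", [f"spec{i + 1:04d}" for i in range(n)])

    is_field = rng.random(n) < cfg.field_fraction
    df["origin"] = np.where(is_field, "field", "museum")
    museum_labels = [f"museum{m + 1}" for m in range(cfg.n_collections)]
    df["collection"] = np.where(
        is_field, "field", rng.choice(museum_labels, size=n)
    )

    lat_c = df["latitude"] - df["latitude"].mean()
    n_trunc = 0
    for c in CHANNELS:
        hab_c = df[f"habitat_{c}"] - df[f"habitat_{c}"].mean()
        fur = (
            _FUR_BASE[c]
            + cfg.b_hab * hab_c
            + cfg.b_lat * lat_c
            + cfg.field_offset * is_field
            + df["species"].map(bm[c]).to_numpy()
            + rng.normal(0.0, cfg.noise_sd, n)
        )
        n_trunc += int(np.sum((fur < 0) | (fur > 255)))
        df[f"fur_{c}"] = np.clip(fur, 0.0, 255.0)
    if n_trunc > 0.05 * 3 * n:
        warnings.warn(f"truncation affected {n_trunc} fur values (> 5%)")

    df["fur_L"] = total_reflectance(df["fur_red"], df["fur_green"], df["fur_blue"])
    df["habitat_L"] = total_reflectance(
        df["habitat_red"], df["habitat_green"], df["habitat_blue"]
    )

    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "bm_species_effects": {c: bm[c] for c in CHANNELS},
        "species_counts": dict(zip(species_names, counts.tolist())),
        "n_field": int(is_field.sum()),
        "n_truncated": n_trunc,
    }
    return SyntheticDataset(
        tree=tree,
        newick=tree.to_newick(),
        specimens=df,
        raster=raster,
        period_rasters=periods,
        truth=truth,
    )


def render_patch_images(
    colours: pd.DataFrame,
    outdir: str | Path,
    patch_noise_sd: float = 0.0,
    gain: float = 1.0,
    offset: float = 0.0,
    patch_size: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Write one PNG per specimen: a uniform fur patch plus white/black
    ColorChecker-style reference swatches, all passed through a known linear
    distortion (``gain``/``offset``) that balance correction must invert.

    ``colours`` needs columns id, red, green, blue.  Returns a manifest
    with the image path, patch geometry and observed reference swatches.
    """
    from PIL import Image

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sw = max(patch_size // 4, 8)  # reference swatch side
    records = []
    for _, row in colours.iterrows():
        true_rgb = np.array([row["red"], row["green"], row["blue"]])
        h = patch_size + sw
        img = np.zeros((h, patch_size, 3))
        patch = true_rgb + rng.normal(0.0, patch_noise_sd, (patch_size, patch_size, 3))
        img[:patch_size] = patch
        img[patch_size:, : patch_size // 2] = 255.0  # white swatch
        img[patch_size:, patch_size // 2 :] = 0.0  # black swatch
        distorted = np.clip(img * gain + offset, 0, 255)
        Image.fromarray(np.round(distorted).astype(np.uint8)).save(
            outdir / f"{row['id']}.png"
        )
        records.append(
            {
                "id": row["id"],
                "path": str(outdir / f"{row['id']}.png"),
                "patch_row0": 0,
                "patch_col0": 0,
                "patch_side": patch_size,
                "white_row": patch_size,
                "white_col": 0,
                "black_row": patch_size,
                "black_col": patch_size // 2,
                "swatch_side": sw,
                "white_observed": float(np.clip(255 * gain + offset, 0, 255)),
                "black_observed": float(np.clip(offset, 0, 255)),
            }
        )
    return pd.DataFrame(records)
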