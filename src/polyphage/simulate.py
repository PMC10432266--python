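"""Seeded ground-truth generators for every stage of the pipeline.

Three simulators live here:

* planted-gene genomes (random backbone at a chosen GC with labelled
  telN/repA/parB/capsid/tf intervals) for the locus-mining arm,
* microscopy scenes (elliptical cells on a grid, per-cell designed induction
  states, diffraction-limited 3D Gaussian spots, Poisson-Gaussian camera
  noise, a DAPI-like nuclear channel, and a spot-free negative control) for
  the smFISH arm, and
* Ct tables implying designed fold changes under the comparative-CT model.

The scene model captures the statistical structure the quadrant analysis
assumes — discrete per-cell induction states expressed as several bright
spots against a near-empty uninduced background — not optical realism: the
PSF is an anisotropic Gaussian, there is no photobleaching and segmentation
is taken from the rendered ellipses.  Induced cells draw ``1 + Poisson(mean
- 1)`` spots per active channel, so a designed induced cell always expresses
at least one transcript.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cells import CellMask
from .cluster import DyadConfig
from .mining import AnnotatedContig, GeneFeature
from .spots import ImageStack

__all__ = [
    "GenomePlan",
    "make_genome",
    "random_pair_plans",
    "random_dna",
    "make_repressor_sequence",
    "SceneDesign",
    "Scene",
    "make_scene",
    "make_ct_table",
    "make_viral_load_ct_table",
]

_TWO_PI_32 = (2.0 * math.pi) ** 1.5


# --------------------------------------------------------------------------
# genomes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomePlan:
    """A contig blueprint: backbone length/GC plus planted gene intervals."""

    contig_id: str
    length: int
    planted: tuple[tuple[str, str, int, int], ...]  # (label, strand, start, length)
    gc: float = 0.45
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        ivs = []
        for label, strand, start, length in self.planted:
            end = start + length - 1
            if start < 1 or end > self.length:
                raise ValueError(f"planted {label} at {start}+{length} exceeds contig")
            ivs.append((start, end, label))
        if not self.allow_overlap:
            ivs.sort()
            for (s1, e1, l1), (s2, e2, l2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"planted features {l1} and {l2} overlap")


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def make_genome(plan: GenomePlan) -> tuple[AnnotatedContig, pd.DataFrame]:
    """Render a plan into an annotated contig plus its truth table."""
    rng = np.random.default_rng(plan.seed)
    seq = random_dna(plan.length, plan.gc, rng)
    features = [
        GeneFeature(
            contig_id=plan.contig_id,
            start=start,
            end=start + length - 1,
            strand=strand,
            label=label,
            source="planted",
        )
        for label, strand, start, length in plan.planted
    ]
    truth = pd.DataFrame(
        [
            {
                "contig_id": plan.contig_id,
                "label": f.label,
                "strand": f.strand,
                "start": f.start,
                "end": f.end,
            }
            for f in features
        ]
    )
    contig = AnnotatedContig(
        id=plan.contig_id, length=plan.length, features=features, sequence=seq
    )
    return contig, truth


def random_pair_plans(
    n: int,
    seed: int = 0,
    gap_range: tuple[int, int] = (0, 15_000),
    gene_length: int = 2_000,
    margin: int = 1_000,
) -> list[tuple[GenomePlan, str, int]]:
    """Plans planting one telN/repA pair each: convergent, tandem or divergent.

    Returns ``(plan, orientation, gap_bp)`` triples; a convergent pair with
    gap <= 10 kb is the planted-positive class the miner must recover.
    """
    rng = np.random.default_rng(seed)
    plans = []
    for i in range(n):
        orientation = ("convergent", "tandem", "divergent")[int(rng.integers(3))]
        gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
        s1 = margin
        e1 = s1 + gene_length - 1
        s2 = e1 + gap + 1
        length = s2 + gene_length - 1 + margin
        if orientation == "convergent":
            strands = ("+", "-")
        elif orientation == "tandem":
            strands = ("+", "+") if rng.integers(2) else ("-", "-")
        else:
            strands = ("-", "+")
        # the pair order on the contig is randomized so telN is not always left
        if rng.integers(2):
            planted = (("telN", strands[0], s1, gene_length), ("repA", strands[1], s2, gene_length))
        else:
            planted = (("repA", strands[0], s1, gene_length), ("telN", strands[1], s2, gene_length))
        plans.append(
            (
                GenomePlan(
                    contig_id=f"synthctg_{i:04d}",
                    length=length,
                    planted=planted,
                    seed=int(rng.integers(2**31)),
                ),
                orientation,
                gap,
            )
        )
    return plans


# filler alphabet without G/S/K so the planted dyad motif is the only one
_FILLER = "ACDEFHILMNPQRTVWY"


def make_repressor_sequence(
    seed: int = 0,
    autoproteolytic: bool = True,
    length: int = 230,
    dyad_config: DyadConfig = DyadConfig(),
) -> str:
    """Synthetic cI-like protein with a planted (or destroyed) Ser-Lys dyad.

    The sequence is a random DNA-binding-domain stub followed by an Ala-Gly
    cleavage motif, the catalytic serine and the catalytic lysine at
    lambda-cI-like spacings.  With ``autoproteolytic=False`` the serine is
    mutated to threonine.  Filler residues avoid Gly/Ser/Lys so the motif is
    present or absent unambiguously; this is a synthetic construct, not a
    natural repressor.
    """
    rng = np.random.default_rng(seed)

    def filler(n: int) -> str:
        return "".join(rng.choice(list(_FILLER), size=n))

    stub = filler(110)
    ser = "S" if autoproteolytic else "T"
    core = stub + "AG" + filler(37) + ser + filler(42) + "K"
    if length < len(core):
        raise ValueError(f"length must be >= {len(core)}")
    return core + filler(length - len(core))


# --------------------------------------------------------------------------
# microscopy scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneDesign:
    """Design of a two-channel smFISH scene with known ground truth."""

    n_cells: int = 200
    fractions: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)  # none/a/b/both
    mean_spots: float = 3.0
    amplitude_mean: float = 150.0
    amplitude_sd: float = 20.0
    amplitude_min: float = 50.0
    sigma_xyz: tuple[float, float, float] = (1.4, 1.4, 1.2)
    sigma_jitter: float = 0.1
    cell_background: float = 20.0
    outside_background: float = 4.0
    read_noise_sd: float = 2.0
    nuclear_level: float = 120.0
    shape_zyx: tuple[int, int, int] = (10, 600, 600)
    cell_grid_px: int = 25
    semi_axis_long: tuple[float, float] = (7.0, 10.0)
    semi_axis_short: tuple[float, float] = (3.5, 5.0)
    voxel_size_xy: float = 0.11
    z_step: float = 1.0
    channel_a: str = "A"
    channel_b: str = "B"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9 or min(self.fractions) < 0:
            raise ValueError("class fractions must be non-negative and sum to 1")
        if self.mean_spots < 1:
            raise ValueError("mean_spots must be >= 1")
        nz, ny, nx = self.shape_zyx
        slots = (ny // self.cell_grid_px) * (nx // self.cell_grid_px)
        if self.n_cells > slots:
            raise ValueError(f"n_cells={self.n_cells} exceeds the {slots} grid slots")


def preset(name: str, **overrides) -> SceneDesign:
    """Acquisition presets: 'vibrio' (1 um z-steps) or 'aeromonas' (0.4 um)."""
    if name == "vibrio":
        base = dict(z_step=1.0)
    elif name == "aeromonas":
        base = dict(z_step=0.4)
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return SceneDesign(**base)


@dataclass
class Scene:
    """A rendered scene: stacks by name, the label mask, and the truth tables."""

    stacks: dict[str, ImageStack]
    mask: CellMask
    cells: pd.DataFrame  # cell_id, quadrant class, geometry
    spots: pd.DataFrame  # channel, cell_id, true centre/sigma/amplitude/intensity
    design: SceneDesign


def _ellipse_mask(
    ny: int, nx: int, cy: float, cx: float, a: float, b: float, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(a)) + 1
    y0, y1 = max(0, int(cy) - r), min(ny, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(nx, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (yy[inside], xx[inside])


def _sample_point_in_ellipse(
    rng: np.random.Generator, cy: float, cx: float, a: float, b: float, theta: float,
    shrink: float = 0.8,
) -> tuple[float, float]:
    r = math.sqrt(rng.uniform())
    phi = rng.uniform(0, 2 * math.pi)
    u = shrink * a * r * math.cos(phi)
    v = shrink * b * r * math.sin(phi)
    x = cx + u * math.cos(theta) - v * math.sin(theta)
    y = cy + u * math.sin(theta) + v * math.cos(theta)
    return y, x


def make_scene(design: SceneDesign) -> Scene:
    """Render a scene per the design; deterministic given ``design.seed``.

    Returned stacks: the two analysis channels (named per the design), a
    ``nuclear`` DAPI-like channel, and ``negative_control`` — the identical
    cell field rendered with zero spots in any probed channel.
    """
    rng = np.random.default_rng(design.seed)
    nz, ny, nx = design.shape_zyx
    grid = design.cell_grid_px

    # --- place cells on a jittered grid (no overlap by construction) ---
    rows, cols = ny // grid, nx // grid
    slots = [(r, c) for r in range(rows) for c in range(cols)]
    chosen = [slots[i] for i in rng.permutation(len(slots))[: design.n_cells]]
    label_image = np.zeros((ny, nx), dtype=np.uint16)
    cell_rows = []
    geoms = []
    for cid, (r, c) in enumerate(chosen, start=1):
        a = rng.uniform(*design.semi_axis_long)
        b = rng.uniform(*design.semi_axis_short)
        theta = rng.uniform(0, math.pi)
        slack = max(grid / 2 - a - 1.0, 0.0)
        cy = (r + 0.5) * grid + rng.uniform(-slack, slack)
        cx = (c + 0.5) * grid + rng.uniform(-slack, slack)
        yy, xx = _ellipse_mask(ny, nx, cy, cx, a, b, theta)
        label_image[yy, xx] = cid
        geoms.append((cy, cx, a, b, theta))
        cell_rows.append({"cell_id": cid, "cy": cy, "cx": cx, "a": a, "b": b, "theta": theta})

    # --- designed induction classes ---
    classes = rng.choice(4, size=design.n_cells, p=list(design.fractions))
    class_names = np.array(["none", "a_only", "b_only", "both"])[classes]
    for row, cname in zip(cell_rows, class_names):
        row["quadrant"] = cname

    # --- noiseless signal volumes ---
    inside = label_image > 0
    base = np.where(inside, design.cell_background, design.outside_background)
    base3d = np.broadcast_to(base, (nz, ny, nx)).astype(float)
    signal = {design.channel_a: np.zeros((nz, ny, nx)), design.channel_b: np.zeros((nz, ny, nx))}
    spot_rows = []
    for cid, (geom, cname) in enumerate(zip(geoms, class_names), start=1):
        cy, cx, a, b, theta = geom
        active = {
            design.channel_a: cname in ("a_only", "both"),
            design.channel_b: cname in ("b_only", "both"),
        }
        for ch, on in active.items():
            if not on:
                continue
            n_spots = 1 + int(rng.poisson(design.mean_spots - 1))
            for _ in range(n_spots):
                y, x = _sample_point_in_ellipse(rng, cy, cx, a, b, theta)
                z = rng.uniform(2.0, nz - 3.0)
                amp = max(
                    design.amplitude_min,
                    float(rng.normal(design.amplitude_mean, design.amplitude_sd)),
                )
                jit = 1.0 + design.sigma_jitter * rng.uniform(-1, 1, size=3)
                sx, sy, sz = np.array(design.sigma_xyz) * jit
                _render_gaussian(signal[ch], z, y, x, amp, sz, sy, sx)
                spot_rows.append(
                    {
                        "channel": ch,
                        "cell_id": cid,
                        "x": x,
                        "y": y,
                        "z": z,
                        "sigma_x": sx,
                        "sigma_y": sy,
                        "sigma_z": sz,
                        "amplitude": amp,
                        "integrated_intensity": amp * _TWO_PI_32 * sx * sy * sz,
                    }
                )

    # --- camera noise: Poisson shot noise + Gaussian read noise ---
    def acquire(photon_image: np.ndarray) -> np.ndarray:
        counts = rng.poisson(photon_image).astype(float)
        counts += rng.normal(0.0, design.read_noise_sd, size=counts.shape)
        return np.clip(counts, 0, None)

    def stack(v: np.ndarray, name: str) -> ImageStack:
        return ImageStack(
            voxels=v, channel=name,
            voxel_size_xy=design.voxel_size_xy, z_step=design.z_step,
        )

    stacks = {
        design.channel_a: stack(acquire(base3d + signal[design.channel_a]), design.channel_a),
        design.channel_b: stack(acquire(base3d + signal[design.channel_b]), design.channel_b),
        "nuclear": stack(
            acquire(np.broadcast_to(
                np.where(inside, design.nuclear_level, design.outside_background), (nz, ny, nx)
            ).astype(float)),
            "nuclear",
        ),
        "negative_control": stack(acquire(base3d.copy()), "negative_control"),
    }
    spots_df = pd.DataFrame(
        spot_rows,
        columns=[
            "channel", "cell_id", "x", "y", "z",
            "sigma_x", "sigma_y", "sigma_z", "amplitude", "integrated_intensity",
        ],
    )
    return Scene(
        stacks=stacks,
        mask=CellMask(label_image=label_image),
        cells=pd.DataFrame(cell_rows),
        spots=spots_df,
        design=design,
    )


def _render_gaussian(
    volume: np.ndarray, z: float, y: float, x: float,
    amplitude: float, sz: float, sy: float, sx: float, extent_sigmas: float = 4.0,
) -> None:
    nz, ny, nx = volume.shape
    z0, z1 = max(0, int(z - extent_sigmas * sz)), min(nz, int(z + extent_sigmas * sz) + 2)
    y0, y1 = max(0, int(y - extent_sigmas * sy)), min(ny, int(y + extent_sigmas * sy) + 2)
    x0, x1 = max(0, int(x - extent_sigmas * sx)), min(nx, int(x + extent_sigmas * sx) + 2)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1, dtype=float),
        np.arange(y0, y1, dtype=float),
        np.arange(x0, x1, dtype=float),
        indexing="ij",
    )
    volume[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(
        -((zz - z) ** 2 / (2 * sz**2) + (yy - y) ** 2 / (2 * sy**2) + (xx - x) ** 2 / (2 * sx**2))
    )


# --------------------------------------------------------------------------
# qPCR tables
# --------------------------------------------------------------------------

def make_ct_table(
    folds: Mapping[str, float],
    replicate_sd: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
    base_target_ct: float = 24.0,
    base_ref_ct: float = 15.0,
    target: str = "phage",
    reference: str = "rpoB",
    control_sample: str = "control",
) -> pd.DataFrame:
    """Ct table implying the designed delta-delta-Ct fold changes.

    For each condition with designed fold f, the treated target Ct is shifted
    by ``-log2(f)`` relative to the control while the reference gene stays
    put, so ``fold_change_ddct`` recovers f exactly at ``replicate_sd = 0``.
    """
    if min(folds.values()) <= 0:
        raise ValueError("designed folds must be positive")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample: str, gene: str, ct: float) -> None:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": sample,
                    "target": gene,
                    "ct": ct + rng.normal(0.0, replicate_sd),
                    "replicate": rep,
                }
            )

    emit(control_sample, target, base_target_ct)
    emit(control_sample, reference, base_ref_ct)
    for condition, fold in folds.items():
        emit(condition, target, base_target_ct - math.log2(fold))
        emit(condition, reference, base_ref_ct)
    return pd.DataFrame(rows)


def make_viral_load_ct_table(
    folds: Mapping[str, float],
    ct_uninduced: float = 25.0,
    replicate_sd: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
    target: str = "phage",
    uninduced_sample: str = "water",
) -> pd.DataFrame:
    """Ct table for the no-reference viral-load variant (2**(Ct_un - Ct_ind))."""
    if min(folds.values()) <= 0:
        raise ValueError("designed folds must be positive")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample: str, ct: float) -> None:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "ct": ct + rng.normal(0.0, replicate_sd),
                    "replicate": rep,
                }
            )

    emit(uninduced_sample, ct_uninduced)
    for condition, fold in folds.items():
        emit(condition, ct_uninduced - math.log2(fold))
    return pd.DataFrame(rows)
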