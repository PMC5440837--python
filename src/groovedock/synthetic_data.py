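"""Synthetic inputs for every pipeline stage.

Structures
----------
Idealized transmembrane helices (Calpha + pseudo-Cbeta) assembled into:

* a 12-position ring bundle with one position omitted — the "short" homolog
  whose 11 helices leave a lateral groove (emulating bilaterian ND2);
* the "long" homolog: identical coordinates plus three extra N-terminal
  helices, one of which (the filler) occupies the groove position (emulating
  bacterial NuoN);
* a four-subunit receptor fixture whose four-helix subunits (M1, short pore
  M2, M3, M4) pack with pseudo four-fold symmetry, M4 outermost and radially
  protruding, flanked by the neighbouring subunit's M1/M3 — the geometry that
  lets the short bundle's groove walls slot in around M4 at a single
  well-defined rotation angle.

Assays
------
Two-channel widefield-like cell images with a tunable co-localized puncta
fraction, Gaussian PSF, background and Poisson/Gaussian noise; and split-
fluorophore (BiFC-style) per-cell intensity tables with tunable reporter
strength over background.

All generators are pure functions of their parameter objects including the
seed: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .coloc import TwoChannelImage
from .docking import (
    RigidTransform,
    _centre_trim,
    count_clashes,
    ClashParams,
    fit_helix_axis,
    kabsch,
    rotation_about_axis,
)
from .structio import Atom, HelixSegment, Structure, select

__all__ = [
    "HelixSpec",
    "HelixPlacement",
    "BundleSpec",
    "Bundle",
    "ColocSimParams",
    "BiFCSimParams",
    "build_ideal_helix",
    "ring_bundle_spec",
    "build_bundle",
    "make_long_short_pair",
    "LongShortPair",
    "make_receptor_fixture",
    "ReceptorFixture",
    "plant_complex",
    "PlantedScene",
    "simulate_coloc_images",
    "SimulatedCell",
    "simulate_bifc",
    "write_coloc_batch",
]


# ---------------------------------------------------------------------------
# Ideal helices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """Idealized alpha-helix: Calpha on a regular helix around a straight axis.

    rise 1.5 A/residue and twist 100 deg/residue are the canonical alpha-helix
    values; helix_radius is the Calpha distance from the axis.
    """

    n_residues: int
    rise: float = 1.5
    twist: float = 100.0
    helix_radius: float = 2.3
    axis_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("a helix needs at least 4 residues")
        if self.rise <= 0 or self.helix_radius <= 0:
            raise ValueError("rise and helix_radius must be positive")
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("axis_direction must have unit norm")


CB_OFFSET = 1.5  # pseudo-Cbeta sits this far radially outward from Calpha


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal (u, v) spanning the plane normal to the axis."""
    d = np.asarray(direction, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def build_ideal_helix(
    spec: HelixSpec,
    chain_id: str = "A",
    start_residue: int = 1,
    residue_name: str = "ALA",
    with_cb: bool = True,
) -> Structure:
    """Calpha (+ pseudo-Cbeta) trace of one ideal helix, sequential numbering."""
    point = np.asarray(spec.axis_point, dtype=float)
    direction = np.asarray(spec.axis_direction, dtype=float)
    u, v = _axis_frame(direction)
    atoms: list[Atom] = []
    for i in range(spec.n_residues):
        theta = np.deg2rad(spec.phase + i * spec.twist)
        radial = np.cos(theta) * u + np.sin(theta) * v
        ca = point + i * spec.rise * direction + spec.helix_radius * radial
        resnum = start_residue + i
        atoms.append(Atom("CA", "C", ca, resnum, residue_name, chain_id))
        if with_cb:
            cb = ca + CB_OFFSET * radial
            atoms.append(Atom("CB", "C", cb, resnum, residue_name, chain_id))
    return Structure(atoms, id=f"helix-{chain_id}{start_residue}")


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixPlacement:
    label: str
    spec: HelixSpec
    start_residue: int


@dataclass(frozen=True)
class BundleSpec:
    """Labelled helices on a ring; `groove_gap` names the omitted position."""

    placements: tuple[HelixPlacement, ...]
    ring_radius: float
    groove_gap: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "placements", tuple(self.placements))
        axes = [
            (tuple(p.spec.axis_point[:2]), tuple(p.spec.axis_direction))
            for p in self.placements
        ]
        pts = [a[0] for a in axes]
        if len(set(pts)) != len(pts):
            raise ValueError("helix axes must be mutually non-coincident")


class Bundle(NamedTuple):
    structure: Structure
    helices: list[HelixSegment]
    spec: BundleSpec

    def helix(self, label: str) -> HelixSegment:
        for seg in self.helices:
            if seg.label == label:
                return seg
        raise KeyError(label)


# Geometry of the default fixtures (Angstrom / degrees).  The ring spacing
# keeps groove-wall-to-guest atom clearances above the 2.5 A clash cutoff at
# the docked pose, while the receptor guard helices (below) sit close enough
# that a one-degree mis-rotation of a docked bundle already registers clashes.
RING_POSITIONS = 12
GAP_INDEX = 3
HELIX_RESIDUES = 24
RING_SPACING = 10.5
RING_RADIUS = RING_SPACING / (2.0 * np.sin(np.pi / RING_POSITIONS))
RESIDUES_PER_SLOT = 50  # residue numbering block per ring position


def _ring_helix_spec(
    centre: np.ndarray,
    azimuth_deg: float,
    radius: float,
    up: bool,
    n_residues: int = HELIX_RESIDUES,
    phase: float = 0.0,
) -> HelixSpec:
    """Vertical helix at a ring position, z-centred, up or down direction."""
    az = np.deg2rad(azimuth_deg)
    xy = centre + radius * np.array([np.cos(az), np.sin(az)])
    half = (n_residues - 1) * 1.5 / 2.0
    if up:
        point = (float(xy[0]), float(xy[1]), -half)
        direction = (0.0, 0.0, 1.0)
    else:
        point = (float(xy[0]), float(xy[1]), half)
        direction = (0.0, 0.0, -1.0)
    return HelixSpec(
        n_residues=n_residues, axis_point=point, axis_direction=direction, phase=phase
    )


def ring_bundle_spec(
    n_positions: int = RING_POSITIONS,
    gap_index: int | None = GAP_INDEX,
    ring_radius: float = RING_RADIUS,
    n_residues: int = HELIX_RESIDUES,
) -> BundleSpec:
    """Ring of antiparallel helices; `gap_index` names the omitted position.

    Present positions are labelled TM1..TMk in ring order (skipping the gap);
    the gap itself is labelled TMF for use by :func:`make_long_short_pair`.
    """
    centre = np.zeros(2)
    placements: list[HelixPlacement] = []
    tm = 0
    for pos in range(n_positions):
        azimuth = 360.0 * pos / n_positions
        spec = _ring_helix_spec(centre, azimuth, ring_radius, up=(pos % 2 == 0),
                                n_residues=n_residues)
        if gap_index is not None and pos == gap_index:
            label = "TMF"
        else:
            tm += 1
            label = f"TM{tm}"
        placements.append(
            HelixPlacement(label=label, spec=spec, start_residue=RESIDUES_PER_SLOT * pos + 1)
        )
    groove_gap = "TMF" if gap_index is not None else None
    return BundleSpec(tuple(placements), ring_radius=ring_radius, groove_gap=groove_gap)


def build_bundle(spec: BundleSpec, chain_id: str = "A") -> Bundle:
    """Realize a bundle; the groove-gap helix, if named, is omitted.

    Raises if any inter-helix Calpha pair comes closer than 3.0 A.
    """
    atoms: list[Atom] = []
    helices: list[HelixSegment] = []
    ca_sets: list[np.ndarray] = []
    for placement in spec.placements:
        if placement.label == spec.groove_gap:
            continue
        helix = build_ideal_helix(
            placement.spec, chain_id=chain_id, start_residue=placement.start_residue
        )
        atoms.extend(helix.atoms)
        helices.append(
            HelixSegment(
                chain_id,
                placement.start_residue,
                placement.start_residue + placement.spec.n_residues - 1,
                label=placement.label,
            )
        )
        ca_sets.append(helix.ca_coords())
    for i in range(len(ca_sets)):
        for j in range(i + 1, len(ca_sets)):
            d = np.linalg.norm(ca_sets[i][:, None, :] - ca_sets[j][None, :, :], axis=2)
            if d.min() < 3.0:
                raise ValueError(
                    f"helices {helices[i].label} and {helices[j].label} overlap "
                    f"(min Calpha distance {d.min():.2f} A)"
                )
    return Bundle(Structure(atoms, id="bundle"), helices, spec)


class LongShortPair(NamedTuple):
    long: Bundle
    short: Bundle
    filler: HelixSegment


# The two peripheral extra helices of the long homolog sit outside the ring
# flanking the filler position.
EXTRA_SLOTS = (12, 13)
EXTRA_AZIMUTH_OFFSETS = (-16.0, 16.0)


def make_long_short_pair(spec: BundleSpec | None = None) -> LongShortPair:
    """Long (groove-filled, +3 helices) and short (groove-bearing) bundles.

    The long bundle carries the filler helix at the groove position plus two
    peripheral helices outside the ring; the short bundle is the identical
    structure with those three helices removed, so the pair superposes exactly
    on shared atoms.
    """
    if spec is None:
        spec = ring_bundle_spec()
    if spec.groove_gap is None:
        raise ValueError("spec must name a groove_gap position")
    short = build_bundle(spec)

    gap = next(p for p in spec.placements if p.label == spec.groove_gap)
    gap_azimuth = np.degrees(
        np.arctan2(gap.spec.axis_point[1], gap.spec.axis_point[0])
    )
    extras: list[HelixPlacement] = [gap]
    for slot, daz in zip(EXTRA_SLOTS, EXTRA_AZIMUTH_OFFSETS):
        extras.append(
            HelixPlacement(
                label=f"TMX{slot - EXTRA_SLOTS[0] + 1}",
                spec=_ring_helix_spec(
                    np.zeros(2),
                    gap_azimuth + daz,
                    spec.ring_radius + RING_SPACING,
                    up=(slot % 2 == 0),
                ),
                start_residue=RESIDUES_PER_SLOT * slot + 1,
            )
        )
    # groove_gap=None keeps the filler in the build
    long_spec = BundleSpec(
        tuple(spec.placements) + tuple(extras[1:]), spec.ring_radius, groove_gap=None
    )
    long = build_bundle(long_spec)
    filler = long.helix(spec.groove_gap)
    return LongShortPair(long=long, short=short, filler=filler)


# ---------------------------------------------------------------------------
# Receptor fixture
# ---------------------------------------------------------------------------

# Subunit-local geometry (outward direction = +x): M4 protrudes at the
# largest pore radius; M1/M3 sit behind and lateral to their own M4, roughly
# equidistant from the M4 axis and from the groove-wall helices of a docked
# bundle — the guard helices that pin the docked bundle's rotation angle.
# M4's helical phase of -90 deg makes the filler->M4 superposition place a
# docked bundle exactly in the outward mating orientation at scan angle zero.
M4_PORE_RADIUS = 22.5
M4_PHASE = -90.0
M2_PORE_RADIUS = 5.1
M2_RESIDUES = 18
# Guard positions relative to the subunit's M4 (outward = +x).  The offsets
# are asymmetric because helix handedness breaks mirror symmetry: each guard
# is placed so a docked bundle's groove wall clears it by barely more than
# the 2.5 A clash cutoff at the mating orientation and clashes within ~1 deg
# of mis-rotation either way.
M3_OFFSET = (-6.13, 7.66)  # +y side guard
M1_OFFSET = (-6.57, -7.52)  # -y side guard
RECEPTOR_CHAINS = "ABCD"
RECEPTOR_NUMBERING = {"M1": 700, "M2": 740, "M3": 770, "M4": 813}


class ReceptorFixture(NamedTuple):
    structure: Structure
    m4_segments: list[HelixSegment]

    @property
    def pore_axis(self) -> tuple[np.ndarray, np.ndarray]:
        return np.zeros(3), np.array([0.0, 0.0, 1.0])


def make_receptor_fixture(n_subunits: int = 4) -> ReceptorFixture:
    """Four-helix subunits with pseudo n-fold symmetry about the pore (z) axis.

    Per subunit: short pore-facing M2 innermost, M1 and M3 at mid radius, M4
    outermost and radially protruding.  M4 is numbered 813-836 to match the
    registered GluN1-M4 landmark.
    """
    if n_subunits < 2:
        raise ValueError("need at least 2 subunits")
    atoms: list[Atom] = []
    m4_segments: list[HelixSegment] = []
    for k in range(n_subunits):
        chain = RECEPTOR_CHAINS[k] if k < len(RECEPTOR_CHAINS) else chr(ord("E") + k - 4)
        alpha = 360.0 * k / n_subunits
        a = np.deg2rad(alpha)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        m4_xy = rot @ np.array([M4_PORE_RADIUS, 0.0])
        m1_xy = rot @ (np.array([M4_PORE_RADIUS, 0.0]) + np.array(M1_OFFSET))
        m3_xy = rot @ (np.array([M4_PORE_RADIUS, 0.0]) + np.array(M3_OFFSET))
        m2_xy = rot @ np.array([M2_PORE_RADIUS, 0.0])

        def helix_at(xy: np.ndarray, up: bool, n_res: int, phase: float = 0.0) -> HelixSpec:
            half = (n_res - 1) * 1.5 / 2.0
            return HelixSpec(
                n_residues=n_res,
                axis_point=(float(xy[0]), float(xy[1]), -half if up else half),
                axis_direction=(0.0, 0.0, 1.0) if up else (0.0, 0.0, -1.0),
                phase=phase,
            )

        # The pore-lining M2 is a thin Calpha-only helix; M4's phase is fixed
        # so the groove-filler superposition is rotation-free (see above).
        # Helix phases co-rotate with the subunit azimuth (sign follows the
        # helix direction) so the fixture is exactly n-fold symmetric.
        for name, xy, up, n_res, phase0, cb in (
            ("M1", m1_xy, True, HELIX_RESIDUES, 0.0, True),
            ("M2", m2_xy, False, M2_RESIDUES, 0.0, False),
            ("M3", m3_xy, True, HELIX_RESIDUES, 0.0, True),
            ("M4", m4_xy, False, HELIX_RESIDUES, M4_PHASE, True),
        ):
            phase = phase0 + alpha if up else phase0 - alpha
            start = RECEPTOR_NUMBERING[name]
            helix = build_ideal_helix(
                helix_at(xy, up, n_res, phase), chain_id=chain, start_residue=start,
                with_cb=cb,
            )
            atoms.extend(helix.atoms)
            if name == "M4":
                m4_segments.append(
                    HelixSegment(chain, start, start + n_res - 1, label=f"{chain}-M4")
                )
    return ReceptorFixture(Structure(atoms, id="receptor"), m4_segments)


# ---------------------------------------------------------------------------
# Planted ground-truth complexes
# ---------------------------------------------------------------------------

class PlantedScene(NamedTuple):
    bundle: Structure
    receptor: Structure
    ground_truth: RigidTransform
    true_angle: float


def plant_complex(
    pair: LongShortPair,
    receptor: ReceptorFixture,
    target_m4: HelixSegment | None = None,
    true_angle: float = 0.0,
    seed: int = 0,
) -> PlantedScene:
    """Place the short bundle so its groove receives the target M4 helix at
    the stated rotation about the M4 axis.

    The canonical pose superposes the (virtual) filler helix onto M4; the
    bundle and the receptor's non-target helices are then rotated in tandem
    about the M4 axis by `true_angle`, so every angle in [0, 360) yields a
    geometrically admissible scene whose clash-scan minimum sits at
    `true_angle`.  Returns the exact transform applied to the short bundle.
    """
    del seed  # placement is deterministic; kept for interface uniformity
    if target_m4 is None:
        target_m4 = receptor.m4_segments[0]
    filler_ca = select(pair.long.structure, pair.filler.chain_id, pair.filler).ca_coords()
    m4_ca = select(receptor.structure, target_m4.chain_id, target_m4).ca_coords()
    fc, mc = _centre_trim(filler_ca, m4_ca)
    anchor, _ = kabsch(fc, mc)
    axis_point, axis_dir = fit_helix_axis(m4_ca)
    spin = rotation_about_axis(axis_point, axis_dir, true_angle)
    ground_truth = spin.compose(anchor)
    bundle_placed = ground_truth.apply_structure(pair.short.structure)

    core_atoms = []
    for a in receptor.structure.atoms:
        if a.chain_id == target_m4.chain_id and a.residue_number in target_m4:
            core_atoms.append(a)
        else:
            pos = spin.apply(a.position[None, :])[0]
            core_atoms.append(
                Atom(a.name, a.element, pos, a.residue_number, a.residue_name, a.chain_id)
            )
    receptor_scene = Structure(core_atoms, id=receptor.structure.id)

    hard = count_clashes(bundle_placed, receptor_scene, ClashParams(cutoff=2.0))
    if hard > 0:
        raise ValueError(
            f"planted pose at {true_angle:.1f} deg has {hard} hard clashes (< 2.0 A)"
        )
    return PlantedScene(bundle_placed, receptor_scene, ground_truth, true_angle)


# ---------------------------------------------------------------------------
# Co-localization image simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocSimParams:
    """Two-channel puncta images with a known co-localized fraction.

    `coloc_fraction` rho is the fraction of puncta shared between channels;
    the rest are placed independently.  Puncta are blurred with a Gaussian
    PSF, background is added, then Poisson photon noise and/or Gaussian read
    noise.  Defaults emulate a modest widefield field of view: 128x128 px,
    40 puncta/channel, PSF sigma 1.5 px, background 20 counts, peak signal
    roughly 10x background.
    """

    n_cells: int = 30
    image_shape: tuple[int, int] = (128, 128)
    coloc_fraction: float = 0.5
    puncta_count: int = 40
    psf_sigma: float = 1.5
    background: float = 20.0
    amplitude: float = 3000.0
    noise_model: str = "poisson"  # "poisson", "gaussian", "none"
    gaussian_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.n_cells <= 0 or self.puncta_count <= 0:
            raise ValueError("counts must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


class SimulatedCell(NamedTuple):
    cell_id: str
    image: TwoChannelImage
    true_coloc_fraction: float


def _render_channel(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    psf_sigma: float,
    background: float,
) -> np.ndarray:
    img = np.zeros(shape)
    for (r, c), amp in zip(positions, amplitudes):
        img[int(r), int(c)] += amp
    img = ndimage.gaussian_filter(img, psf_sigma)
    return img + background


def simulate_coloc_images(p: ColocSimParams) -> list[SimulatedCell]:
    """Per-cell two-channel images; deterministic under the seed."""
    rng = np.random.default_rng(p.seed)
    n_shared = int(round(p.coloc_fraction * p.puncta_count))
    cells: list[SimulatedCell] = []
    shape = tuple(p.image_shape)
    for c in range(p.n_cells):
        def draw(n: int) -> np.ndarray:
            pos = np.column_stack(
                [rng.integers(0, shape[0], n), rng.integers(0, shape[1], n)]
            )
            return pos

        shared_pos = draw(n_shared)
        shared_amp = p.amplitude * rng.lognormal(mean=0.0, sigma=0.25, size=n_shared)
        own1_pos = draw(p.puncta_count - n_shared)
        own1_amp = p.amplitude * rng.lognormal(0.0, 0.25, p.puncta_count - n_shared)
        own2_pos = draw(p.puncta_count - n_shared)
        own2_amp = p.amplitude * rng.lognormal(0.0, 0.25, p.puncta_count - n_shared)

        ch1 = _render_channel(
            shape,
            np.vstack([shared_pos, own1_pos]),
            np.concatenate([shared_amp, own1_amp]),
            p.psf_sigma,
            p.background,
        )
        ch2 = _render_channel(
            shape,
            np.vstack([shared_pos, own2_pos]),
            np.concatenate([shared_amp, own2_amp]),
            p.psf_sigma,
            p.background,
        )
        if p.noise_model == "poisson":
            ch1 = rng.poisson(ch1).astype(float)
            ch2 = rng.poisson(ch2).astype(float)
        elif p.noise_model == "gaussian":
            ch1 = np.clip(ch1 + rng.normal(0.0, p.gaussian_sigma, shape), 0, None)
            ch2 = np.clip(ch2 + rng.normal(0.0, p.gaussian_sigma, shape), 0, None)
        cells.append(
            SimulatedCell(
                cell_id=f"cell{c:03d}",
                image=TwoChannelImage(ch1=ch1, ch2=ch2),
                true_coloc_fraction=p.coloc_fraction,
            )
        )
    return cells


def write_coloc_batch(cells: list[SimulatedCell], outdir: str | Path, group: str = "sim") -> Path:
    """Write one two-page TIFF per cell plus a manifest TSV and truth JSON.

    Returns the manifest path (columns: cell_id, group, path).
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for cell in cells:
        path = outdir / f"{cell.cell_id}.tif"
        tifffile.imwrite(
            path, np.stack([cell.image.ch1, cell.image.ch2]).astype(np.float32)
        )
        rows.append({"cell_id": cell.cell_id, "group": group, "path": str(path)})
        truth[cell.cell_id] = cell.true_coloc_fraction
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# BiFC table simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiFCSimParams:
    """Per-cell background / Cy3 / Venus intensities.

    `reporter_fold` is the true Venus intensity as a multiple of the cell's
    background; `cy3_fold` likewise for the Cy3 transfection marker.
    Multiplicative noise has coefficient of variation `noise_cv`.
    """

    n_cells: int = 30
    background_mean: float = 100.0
    reporter_fold: float = 5.0
    cy3_fold: float = 6.0
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reporter_fold < 0 or self.cy3_fold < 0:
            raise ValueError("fold parameters must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_cells <= 0 or self.background_mean <= 0:
            raise ValueError("n_cells and background_mean must be positive")


def simulate_bifc(p: BiFCSimParams, group: str = "sim") -> pd.DataFrame:
    """Table of per-cell intensities: cell_id, group, background, cy3, venus."""
    rng = np.random.default_rng(p.seed)

    def noisy(base: np.ndarray) -> np.ndarray:
        if p.noise_cv == 0:
            return base
        factor = rng.normal(1.0, p.noise_cv, size=len(base))
        return base * np.clip(factor, 0.05, None)

    background = noisy(np.full(p.n_cells, p.background_mean))
    cy3 = noisy(p.cy3_fold * background)
    venus = noisy(p.reporter_fold * background)
    return pd.DataFrame(
        {
            "cell_id": [f"{group}-{i:03d}" for i in range(p.n_cells)],
            "group": group,
            "background": background,
            "cy3": cy3,
            "venus": venus,
        }
    )
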