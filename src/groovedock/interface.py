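"""Interface quantification: solvent-accessible surface area (Shrake-Rupley),
buried contact area by the difference formula, contact residue pairs and
groove-lining helix identification.

Buried (contact) surface area of a complex A:B is

    buried = [SASA(A) + SASA(B)] - SASA(A u B)

summed over both partners, i.e. the accessible area lost on complex
formation.  SASA uses a deterministic golden-section spiral point set on each
expanded sphere (atom radius + probe), so results are reproducible without a
random seed; quadrature error falls off with the point count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import HelixSegment, Structure, select

logger = logging.getLogger(__name__)

__all__ = [
    "SasaParams",
    "InterfaceResult",
    "sasa",
    "buried_area",
    "contact_pairs",
    "groove_lining",
    "DEFAULT_RADII",
]

# Van der Waals radii by element (Angstrom).  Reduced Calpha-only /
# Calpha+pseudo-Cbeta models inflate CA to mimic residue bulk.
DEFAULT_RADII: dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
REDUCED_CA_RADIUS = 2.4


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    reduced_ca_radius: float = REDUCED_CA_RADIUS

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 64:
            raise ValueError("n_sphere_points must be >= 64")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral on the unit sphere."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radii(s: Structure, p: SasaParams) -> np.ndarray:
    """Per-heavy-atom radius.  In reduced (CA/CB-only) models CA is inflated."""
    heavy = [a for a in s.atoms if a.is_heavy]
    reduced = all(a.name in ("CA", "CB") for a in heavy)
    radii = []
    for a in heavy:
        if reduced and a.name == "CA":
            radii.append(p.reduced_ca_radius)
            continue
        r = p.radii_table.get(a.element.upper())
        if r is None:
            raise KeyError(
                f"no radius for element {a.element!r} "
                f"(atom {a.name} {a.chain_id}{a.residue_number})"
            )
        radii.append(r)
    return np.array(radii)


def sasa(s: Structure, p: SasaParams = SasaParams()) -> np.ndarray:
    """Per-heavy-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    For each atom, test points on its expanded sphere (radius + probe) are
    kept if outside every other atom's expanded sphere; the accessible
    fraction times the expanded-sphere area is the atom's SASA.
    """
    if len(s) == 0:
        raise ValueError("structure is empty")
    coords = s.heavy_coords
    radii = atom_radii(s, p)
    expanded = radii + p.probe_radius
    unit = _sphere_points(p.n_sphere_points)
    tree = cKDTree(coords)
    r_max = expanded.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        # any neighbour whose expanded sphere could cover a test point
        neigh = tree.query_ball_point(coords[i], expanded[i] + r_max)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(p.n_sphere_points, dtype=bool)
        if neigh:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            accessible = ~np.any(d2 < (expanded[neigh] ** 2)[None, :], axis=1)
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


@dataclass
class InterfaceResult:
    buried_area: float
    per_partner_buried: tuple[float, float]
    contacts: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    groove_lining: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "buried_area": self.buried_area,
            "per_partner_buried": list(self.per_partner_buried),
            "contacts": [[list(a), list(b)] for a, b in self.contacts],
            "groove_lining": list(self.groove_lining),
        }


def buried_area(a: Structure, b: Structure, p: SasaParams = SasaParams()) -> InterfaceResult:
    """Buried surface area of the a:b interface by the difference formula.

    Per-partner split comes from the per-atom SASA differences; tiny negative
    quadrature residue is clamped to zero with a warning.
    """
    sa = sasa(a, p)
    sb = sasa(b, p)
    combined = Structure(
        list(a.atoms) + [at for at in b.atoms], id=f"{a.id}+{b.id}"
    )
    sab = sasa(combined, p)
    n_a = int(sum(1 for at in a.atoms if at.is_heavy))
    da = sa - sab[:n_a]
    db = sb - sab[n_a:]
    ba, bb = float(da.sum()), float(db.sum())
    total = ba + bb
    if total < 0:
        logger.warning("buried area %.3f A^2 below zero (quadrature noise); clamping", total)
        ba = max(ba, 0.0)
        bb = max(bb, 0.0)
    return InterfaceResult(buried_area=ba + bb, per_partner_buried=(ba, bb))


def contact_pairs(
    a: Structure, b: Structure, cutoff: float = 4.5
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Unique residue pairs with any inter-body heavy-atom distance < cutoff."""
    ca, cb = a.heavy_coords, b.heavy_coords
    if len(ca) == 0 or len(cb) == 0:
        return []
    heavy_a = [at for at in a.atoms if at.is_heavy]
    heavy_b = [at for at in b.atoms if at.is_heavy]
    tree_b = cKDTree(cb)
    pairs: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    neighbours = cKDTree(ca).query_ball_tree(tree_b, cutoff)
    for i, js in enumerate(neighbours):
        for j in js:
            if np.linalg.norm(ca[i] - cb[j]) < cutoff:
                pairs.add(
                    (
                        (heavy_a[i].chain_id, heavy_a[i].residue_number),
                        (heavy_b[j].chain_id, heavy_b[j].residue_number),
                    )
                )
    return sorted(pairs)


def groove_lining(
    bundle: Structure,
    helices: list[HelixSegment],
    docked_probe: Structure,
    cutoff: float = 4.5,
) -> list[str]:
    """Labels of bundle helices with at least one contact pair to the probe."""
    labels = []
    for seg in helices:
        helix = select(bundle, seg.chain_id, seg)
        if contact_pairs(helix, docked_probe, cutoff):
            labels.append(seg.label)
    return sorted(labels)
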