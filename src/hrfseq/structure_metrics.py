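"""Crystal-structure reference metrics for validating accessibility profiles.

Ribose bead positions (mean of the C1'/C2'/C3'/C4'/O4' atoms), through-space
contact counts within a 14 A radius, per-residue ribose solvent-accessible
surface area from a deterministic dot lattice, and windowed/offset Pearson
correlations against a reactivity profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .reactivity import moving_average

logger = logging.getLogger(__name__)

RIBOSE_BEAD_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

#: atoms summed for per-residue ribose SASA (the full sugar moiety)
RIBOSE_SASA_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O3'", "O4'", "O5'")

# Bondi van der Waals radii (A); frozen here for reproducibility
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "K": 2.75,
    "NA": 2.27,
    "ZN": 1.39,
}
DEFAULT_VDW_RADIUS = 1.70

#: dot counts per density level; level 3 is the default working density
DOT_COUNTS = {1: 122, 2: 362, 3: 962, 4: 2562, 5: 10242}

DEFAULT_CONTACT_RADIUS = 14.0


@dataclass(frozen=True)
class RiboseBead:
    chain: str
    resnum: int
    coord: np.ndarray

    def distance(self, other: "RiboseBead") -> float:
        return float(np.linalg.norm(self.coord - other.coord))


def _highest_occupancy(atom):
    """Resolve a possibly disordered Bio.PDB atom to its best conformer."""
    if atom.is_disordered():
        children = atom.disordered_get_list()
        return max(children, key=lambda a: a.get_occupancy() or 0.0)
    return atom


def ribose_bead_positions(structure, chains=None, residues=None) -> list[RiboseBead]:
    """One bead per residue having all five ribose-ring atoms.

    Parameters
    ----------
    structure:
        A Bio.PDB structure, model or chain.
    chains:
        Optional iterable of chain ids to include.
    residues:
        Optional set/range of residue numbers to include.

    Residues missing any of the five atoms are skipped (and logged).
    """
    beads: list[RiboseBead] = []
    skipped = 0
    for chain in _iter_chains(structure):
        if chains is not None and chain.id not in set(chains):
            continue
        for res in chain:
            resnum = res.id[1]
            if residues is not None and resnum not in residues:
                continue
            coords = []
            for name in RIBOSE_BEAD_ATOMS:
                if name not in res:
                    coords = None
                    break
                coords.append(_highest_occupancy(res[name]).coord)
            if coords is None:
                skipped += 1
                continue
            beads.append(RiboseBead(chain.id, resnum, np.mean(coords, axis=0)))
    if skipped:
        logger.info("skipped %d residue(s) missing ribose atoms", skipped)
    if not beads:
        raise ValueError("no residue in the selection has a complete ribose")
    return beads


def _iter_chains(entity):
    level = getattr(entity, "level", None)
    if level == "C":
        yield entity
    elif level == "M":
        yield from entity
    else:  # structure: first model only
        yield from next(iter(entity))


def through_space_contacts(
    beads: list[RiboseBead],
    radius: float = DEFAULT_CONTACT_RADIUS,
    exclude_adjacent: bool = True,
) -> pd.DataFrame:
    """Number of non-adjacent ribose beads within ``radius`` of each bead.

    Adjacency means residue numbers differing by <= 1 within the same chain;
    numbering gaps therefore count as non-adjacent.
    """
    coords = np.array([b.coord for b in beads])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    counts = np.zeros(len(beads), dtype=int)
    for i, j in pairs:
        bi, bj = beads[i], beads[j]
        if exclude_adjacent and bi.chain == bj.chain and abs(bi.resnum - bj.resnum) <= 1:
            continue
        counts[i] += 1
        counts[j] += 1
    return pd.DataFrame(
        {
            "chain": [b.chain for b in beads],
            "residue": [b.resnum for b in beads],
            "contact_count": counts,
        }
    )


def fibonacci_sphere(n_dots: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n_dots, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_dots
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _element_radius(element: str) -> float:
    r = VDW_RADII.get((element or "").upper())
    if r is None:
        logger.warning(
            "unknown element %r; using default vdW radius %.2f A",
            element,
            DEFAULT_VDW_RADIUS,
        )
        return DEFAULT_VDW_RADIUS
    return r


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_dots: int = DOT_COUNTS[3],
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) via a dot lattice.

    For each atom, dots are placed on its solvent-expanded sphere
    (``r + probe``) along a deterministic spiral lattice; a dot is
    accessible when outside every neighbouring expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe_radius
    sphere = fibonacci_sphere(n_dots)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    sasa = np.zeros(len(coords))
    for i in range(len(coords)):
        neighbors = tree.query_ball_point(coords[i], expanded[i] + max_reach / 2.0)
        neighbors = [j for j in neighbors if j != i]
        dots = coords[i] + expanded[i] * sphere
        if neighbors:
            ncoords = coords[neighbors]
            nrad = expanded[neighbors]
            d2 = ((dots[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nrad**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return sasa


def ribose_sasa(
    structure,
    probe_radius: float = 1.4,
    dot_density: int = 3,
    chains=None,
    residues=None,
    sasa_atoms=RIBOSE_SASA_ATOMS,
) -> pd.DataFrame:
    """Per-residue ribose SASA with every atom of the selection as occluder.

    All atoms of the selected chains enter the occlusion calculation; the
    reported per-residue value sums the SASA of the residue's sugar-moiety
    atoms only.
    """
    n_dots = DOT_COUNTS.get(dot_density)
    if n_dots is None:
        raise ValueError(f"dot_density must be one of {sorted(DOT_COUNTS)}")
    atoms = []
    meta = []  # (chain, resnum, atom name)
    for chain in _iter_chains(structure):
        if chains is not None and chain.id not in set(chains):
            continue
        for res in chain:
            for atom in res:
                atom = _highest_occupancy(atom)
                atoms.append(atom)
                meta.append((chain.id, res.id[1], atom.get_id()))
    if not atoms:
        raise ValueError("no atoms in the selection")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([_element_radius(a.element) for a in atoms])
    per_atom = atom_sasa(coords, radii, probe_radius=probe_radius, n_dots=n_dots)

    df = pd.DataFrame(meta, columns=["chain", "residue", "atom"])
    df["sasa"] = per_atom
    sugar = df[df["atom"].isin(sasa_atoms)]
    if residues is not None:
        sugar = sugar[sugar["residue"].isin(residues)]
    out = (
        sugar.groupby(["chain", "residue"], sort=True)["sasa"]
        .sum()
        .reset_index()
        .rename(columns={"sasa": "ribose_sasa"})
    )
    return out


def correlate_with_structure(
    smoothed_reactivity: np.ndarray,
    structure_metric: np.ndarray,
    window: int = 3,
) -> tuple[float, int]:
    """Pearson R between a reactivity profile and a smoothed structure metric.

    The structure metric gets the same plain 3-nt moving average the paper
    applies to crystal accessibility; positions where either input is NaN
    are dropped.  Returns ``(R, n_shared)``.
    """
    x = np.asarray(smoothed_reactivity, dtype=float)
    y = np.asarray(structure_metric, dtype=float)
    if x.size != y.size:
        raise ValueError("profiles must be aligned on the same positions")
    if window > 1:
        y = moving_average(y, window=window)
    valid = np.isfinite(x) & np.isfinite(y)
    n = int(valid.sum())
    if n < 3:
        raise ValueError(f"only {n} shared positions; need at least 3")
    r, _ = pearsonr(x[valid], y[valid])
    return float(r), n


def offset_correlation(
    signal: np.ndarray,
    reference_metric: np.ndarray,
    offsets=range(-15, 16),
) -> pd.DataFrame:
    """Pearson R between ``signal[p]`` and ``reference_metric[p + d]``.

    Local maxima across ``d`` expose helical periodicity in accessibility.
    Offsets whose overlap has fewer than 3 valid pairs raise.
    """
    x = np.asarray(signal, dtype=float)
    y = np.asarray(reference_metric, dtype=float)
    if x.size != y.size:
        raise ValueError("profiles must be aligned on the same positions")
    rows = []
    for d in offsets:
        if d >= 0:
            xs, ys = x[: x.size - d] if d else x, y[d:]
        else:
            xs, ys = x[-d:], y[: y.size + d]
        if xs.size == 0:
            raise ValueError(f"offset {d} has no overlap with the profile")
        valid = np.isfinite(xs) & np.isfinite(ys)
        n = int(valid.sum())
        if n < 3:
            raise ValueError(f"offset {d}: only {n} shared positions; need at least 3")
        r, _ = pearsonr(xs[valid], ys[valid])
        rows.append((d, float(r), n))
    return pd.DataFrame(rows, columns=["offset", "R", "n"])


def metrics_table(
    structure,
    probe_radius: float = 1.4,
    dot_density: int = 3,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    chains=None,
    residues=None,
) -> pd.DataFrame:
    """Per-residue contact counts and ribose SASA in one table."""
    beads = ribose_bead_positions(structure, chains=chains, residues=residues)
    contacts = through_space_contacts(beads, radius=contact_radius)
    sasa = ribose_sasa(
        structure,
        probe_radius=probe_radius,
        dot_density=dot_density,
        chains=chains,
        residues=residues,
    )
    return contacts.merge(sasa, on=["chain", "residue"], how="outer").sort_values(
        ["chain", "residue"]
    ).reset_index(drop=True)
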