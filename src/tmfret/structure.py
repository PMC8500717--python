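"""Structure-based distance predictions for tmFRET probe pairs.

Given a protein structure, the working-range check for a donor/acceptor site
pair starts from the beta-carbon distance; a better prediction of what a FRET
experiment will see comes from clouds of sterically allowed probe conformers
("rotamer clouds") at each site and the distribution of distances between the
probes' reference points (the Cu ion of the metal acceptor, the carbonyl
carbon of the acridone ring for the Acd donor).

The rotamer sampler here is deliberately simplified: each probe is an
idealized linear chain of coarse pseudo-atoms with fixed bond lengths and
angles, grafted onto the site's backbone and sampled by uniform random
torsions, with conformers rejected on heavy-atom van-der-Waals clashes
against the protein.  It reproduces the size and position of the conformer
clouds, not any particular rotamer library.
"""

from __future__ import annotations

import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "StructureModel",
    "RotamerCloud",
    "VdwPolicy",
    "TIGHT_VDW",
    "LOOSE_VDW",
    "DistanceHistogram",
    "read_pdb",
    "fetch_pdb",
    "beta_carbon_distance",
    "sample_rotamers",
    "sample_dihistidine",
    "cloud_distance_distribution",
    "BuriedSiteError",
]

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class BuriedSiteError(RuntimeError):
    """No sterically allowed probe conformer was found at a site."""


@dataclass
class StructureModel:
    """Heavy-atom protein model backed by a biotite ``AtomArray``."""

    atoms: struc.AtomArray
    source_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")

    def residue_atom(self, res_id: int, atom_name: str,
                     chain: str | None = None) -> np.ndarray:
        """Coordinates of one named atom of one residue."""
        mask = (self.atoms.res_id == res_id) & (self.atoms.atom_name == atom_name)
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise KeyError(f"atom {atom_name} of residue {res_id} not found"
                           + (f" in chain {chain}" if chain else ""))
        return self.atoms.coord[hits[0]].astype(float)

    def residue_name(self, res_id: int, chain: str | None = None) -> str:
        mask = self.atoms.res_id == res_id
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise KeyError(f"residue {res_id} not found")
        return str(self.atoms.res_name[hits[0]])

    def heavy_coords_excluding(self, res_ids: tuple[int, ...],
                               chain: str | None = None) -> np.ndarray:
        """Heavy-atom coordinates, dropping the residues in ``res_ids``.

        The probe replaces the labelled residue's side chain and is covalently
        bonded to its backbone, so the whole residue is excluded from clash
        checks; hydrogens are ignored throughout (crystal structures usually
        lack them).
        """
        heavy = self.atoms.element != "H"
        at_site = np.isin(self.atoms.res_id, res_ids)
        if chain is not None:
            at_site &= self.atoms.chain_id == chain
        keep = heavy & ~at_site
        return self.atoms.coord[keep].astype(float)


def read_pdb(path: str | Path, model: int = 1) -> StructureModel:
    """Read ATOM/HETATM records from a PDB file."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model)
    return StructureModel(atoms=atoms, source_id=Path(path).stem)


def fetch_pdb(pdb_id: str, cache_dir: str | Path | None = None) -> StructureModel:
    """Load a PDB entry from a local cache, downloading from RCSB if needed."""
    pdb_id = pdb_id.upper()
    cache = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "tmfret"
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"{pdb_id}.pdb"
    if not path.exists():
        urllib.request.urlretrieve(_RCSB_URL.format(pdb_id=pdb_id), path)
    return read_pdb(path)


def beta_carbon_distance(model: StructureModel, site_a: int, site_b: int,
                         chain: str | None = None) -> float:
    """Euclidean CB-CB distance between two residues (Angstrom).

    Glycine has no CB; its CA is used instead, with a warning.
    """
    coords = []
    for site in (site_a, site_b):
        try:
            coords.append(model.residue_atom(site, "CB", chain))
        except KeyError:
            if model.residue_name(site, chain) == "GLY":
                warnings.warn(f"residue {site} is glycine; using CA instead of CB")
                coords.append(model.residue_atom(site, "CA", chain))
            else:
                raise
    return float(np.linalg.norm(coords[0] - coords[1]))


# ---------------------------------------------------------------------------
# probe geometry

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Extend the chain a-b-c by one atom with given internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:   # collinear frame; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class ProbeAtom:
    """One pseudo-atom of a probe template in internal coordinates.

    ``frame`` indexes the three preceding atoms (0 = backbone N, 1 = CA,
    2 = CB, then template atoms in order starting at 3) that define the
    placement; ``torsion`` is the fixed dihedral in degrees, or None when the
    dihedral is a rotatable bond to be sampled.
    """

    name: str
    frame: tuple[int, int, int]
    bond: float
    angle: float
    torsion: float | None = None    # None -> rotatable
    reference: bool = False


@dataclass(frozen=True)
class ProbeTemplate:
    kind: str
    atoms: tuple[ProbeAtom, ...]

    @property
    def n_rotatable(self) -> int:
        return sum(1 for a in self.atoms if a.torsion is None)


#: Acd: acridone ring attached directly at CB.  The ring is traced coarsely
#: from the attachment carbon to the carbonyl carbon (the FRET reference
#: point); two rotatable bonds (chi1 and the ring-plane rotation).
ACD_TEMPLATE = ProbeTemplate("acd", (
    ProbeAtom("CG", (0, 1, 2), 1.51, 113.0, None),
    ProbeAtom("AR1", (1, 2, 3), 1.40, 120.0, None),
    ProbeAtom("AR2", (2, 3, 4), 1.40, 120.0, 180.0),
    ProbeAtom("C9", (3, 4, 5), 1.45, 120.0, 0.0, reference=True),
    ProbeAtom("AR3", (3, 4, 5), 1.40, 120.0, 180.0),
))

#: Cu(2+)-TETAC conjugated to cysteine: disulfide plus ethyl linker to the
#: cyclen ring chelating Cu; six rotatable bonds make a wide conformer cloud.
CU_TETAC_TEMPLATE = ProbeTemplate("cu_tetac", (
    ProbeAtom("SG", (0, 1, 2), 1.81, 114.0, None),
    ProbeAtom("SD", (1, 2, 3), 2.04, 104.0, None),
    ProbeAtom("CE", (2, 3, 4), 1.82, 104.0, None),
    ProbeAtom("CZ", (3, 4, 5), 1.53, 112.0, None),
    ProbeAtom("NC", (4, 5, 6), 1.47, 112.0, None),
    ProbeAtom("CU", (5, 6, 7), 2.10, 109.0, None, reference=True),
))

#: Cu(2+) on a histidine imidazole: Cu bound at NE2 with a fixed 2.03 A bond
#: in the ring plane; only chi1/chi2 rotate.
CU_HIS_TEMPLATE = ProbeTemplate("cu_dihis", (
    ProbeAtom("CG", (0, 1, 2), 1.50, 114.0, None),
    ProbeAtom("NE2", (1, 2, 3), 2.20, 165.0, None),
    ProbeAtom("CU", (2, 3, 4), 2.03, 127.0, 180.0, reference=True),
))

PROBE_TEMPLATES = {t.kind: t for t in (ACD_TEMPLATE, CU_TETAC_TEMPLATE, CU_HIS_TEMPLATE)}


@dataclass(frozen=True)
class VdwPolicy:
    """Clash policy for conformer acceptance."""

    cutoff: float        # Angstrom, heavy-atom center distance
    max_clashes: int


TIGHT_VDW = VdwPolicy(cutoff=3.4, max_clashes=0)
LOOSE_VDW = VdwPolicy(cutoff=2.5, max_clashes=5)

MAX_ROTAMERS = 200
ATTEMPT_BUDGET = 10_000


@dataclass
class RotamerCloud:
    """Accepted probe conformers at one site (reference-point coordinates)."""

    site: int
    probe: str
    points: np.ndarray            # (n, 3) reference-point coordinates
    count: int = field(init=False)
    acceptance_rate: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.count = len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized CB position from backbone N, CA, C (used for glycine)."""
    return _place_atom(c, n, ca, 1.53, 110.5, -122.5)


def _site_frame(model: StructureModel, site: int, chain: str | None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = model.residue_atom(site, "N", chain)
    ca = model.residue_atom(site, "CA", chain)
    try:
        cb = model.residue_atom(site, "CB", chain)
    except KeyError:
        cb = _virtual_cb(n, ca, model.residue_atom(site, "C", chain))
    return n, ca, cb


def _build_conformer(frame: tuple[np.ndarray, np.ndarray, np.ndarray],
                     template: ProbeTemplate, torsions: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """All probe-atom coordinates and the reference point for one torsion set."""
    placed = list(frame)
    coords = []
    reference = None
    it = iter(torsions)
    for atom in template.atoms:
        torsion = next(it) if atom.torsion is None else atom.torsion
        a, b, c = (placed[i] for i in atom.frame)
        pos = _place_atom(a, b, c, atom.bond, atom.angle, torsion)
        placed.append(pos)
        coords.append(pos)
        if atom.reference:
            reference = pos
    if reference is None:
        raise ValueError("probe template lacks a reference atom")
    return np.asarray(coords), reference


def sample_rotamers(model: StructureModel, site: int, probe: str,
                    policy: VdwPolicy = TIGHT_VDW, seed: int = 42,
                    chain: str | None = None,
                    max_rotamers: int = MAX_ROTAMERS,
                    attempt_budget: int = ATTEMPT_BUDGET,
                    exclude_sites: tuple[int, ...] = ()) -> RotamerCloud:
    """Sample clash-free probe conformers at a site by random torsions.

    Torsions are drawn uniformly over (-180, 180] per rotatable bond; a
    conformer is accepted when at most ``policy.max_clashes`` probe-atom /
    protein-heavy-atom pairs fall below ``policy.cutoff``.  Deterministic for
    a fixed seed.  Raises :class:`BuriedSiteError` when the attempt budget is
    exhausted without any accepted conformer.
    """
    template = PROBE_TEMPLATES[probe]
    frame = _site_frame(model, site, chain)
    # the labelled residue and its covalent sequence neighbours cannot veto
    # the probe: their backbone is inevitably within any sensible cutoff
    env = model.heavy_coords_excluding(
        (site - 1, site, site + 1, *exclude_sites), chain)
    tree = cKDTree(env)
    rng = np.random.default_rng(seed)

    points = []
    attempts = 0
    while len(points) < max_rotamers and attempts < attempt_budget:
        attempts += 1
        torsions = rng.uniform(-180.0, 180.0, template.n_rotatable)
        coords, reference = _build_conformer(frame, template, torsions)
        clashes = sum(len(hits) for hits in
                      tree.query_ball_point(coords, policy.cutoff))
        if clashes <= policy.max_clashes:
            points.append(reference)
    if not points:
        raise BuriedSiteError(
            f"no clash-free {probe} conformer at site {site} "
            f"within {attempt_budget} attempts")
    return RotamerCloud(site=site, probe=probe, points=np.asarray(points),
                        acceptance_rate=len(points) / attempts)


def sample_dihistidine(model: StructureModel, site_i: int, site_j: int,
                       policy: VdwPolicy = LOOSE_VDW, seed: int = 42,
                       chain: str | None = None,
                       pairing_cutoff: float = 1.0) -> RotamerCloud:
    """Cu(2+) cloud for a di-histidine motif at helix positions i and i +/- 4.

    Each histidine is sampled independently; Cu positions lacking a companion
    from the partner site within ``pairing_cutoff`` (the two imidazoles must
    chelate the same ion) are excluded, and the matched pairs' midpoints form
    the cloud.
    """
    if abs(site_j - site_i) != 4:
        warnings.warn("di-histidine motifs are usually at i and i +/- 4")
    cloud_i = sample_rotamers(model, site_i, "cu_dihis", policy, seed,
                              chain, exclude_sites=(site_j,))
    cloud_j = sample_rotamers(model, site_j, "cu_dihis", policy, seed + 1,
                              chain, exclude_sites=(site_i,))
    tree = cKDTree(cloud_j.points)
    points = []
    for p in cloud_i.points:
        hits = tree.query_ball_point(p, pairing_cutoff)
        for h in hits:
            points.append(0.5 * (p + cloud_j.points[h]))
    if not points:
        raise BuriedSiteError(
            f"no paired Cu position for di-histidine {site_i}/{site_j} "
            f"within {pairing_cutoff} A")
    return RotamerCloud(site=site_i, probe="cu_dihis", points=np.asarray(points),
                        acceptance_rate=min(cloud_i.acceptance_rate,
                                            cloud_j.acceptance_rate))


@dataclass(frozen=True)
class DistanceHistogram:
    """Normalized all-pairs distance histogram between two rotamer clouds."""

    bin_centers: np.ndarray     # Angstrom
    density: np.ndarray         # 1/Angstrom, integrates to 1
    centroid_distance: float
    mean_distance: float
    min_distance: float
    max_distance: float


def cloud_distance_distribution(cloud_a: RotamerCloud, cloud_b: RotamerCloud,
                                bin_width: float = 0.5) -> DistanceHistogram:
    """Histogram of all pairwise reference-point distances between two clouds."""
    if cloud_a.count == 0 or cloud_b.count == 0:
        raise ValueError("both clouds must be non-empty")
    d = np.linalg.norm(cloud_a.points[:, None, :] - cloud_b.points[None, :, :],
                       axis=-1).ravel()
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    density, edges = np.histogram(d, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    centroid_distance = float(np.linalg.norm(cloud_a.centroid - cloud_b.centroid))
    return DistanceHistogram(bin_centers=centers, density=density,
                             centroid_distance=centroid_distance,
                             mean_distance=float(d.mean()),
                             min_distance=float(d.min()),
                             max_distance=float(d.max()))
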