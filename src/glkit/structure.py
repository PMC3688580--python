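"""Coordinate handling and domain-closure geometry.

Two-domain sugar kinases close over their active site by a rigid-body
rotation of the small (lid) domain against the large (Rossmann-core)
domain.  This module quantifies that closure from atomic coordinates:
the mass-center distance between the two domains, the inter-domain
rotation angle between two conformers (Kabsch superposition on the large
domain, then Kabsch on the small domain of the large-aligned models), and
the inventory of inter-domain interactions (hydrogen bonds, cation-π
pairs, like-charge repulsive pairs) under explicit geometric criteria.

File parsing and writing go through gemmi (PDB and mmCIF); in memory a
structure is a plain column-oriented record of atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import AnalysisError, InputError, PartitionError

#: Geometric criteria for inter-domain interaction detection.  Hydrogen
#: bonds use the heavy-atom convention (no hydrogens in typical X-ray
#: models): donor–acceptor distance and the antecedent–donor–acceptor angle.
HBOND_MAX_DIST = 3.5          # Å, donor heavy atom to acceptor
HBOND_MIN_ANGLE = 90.0        # degrees, antecedent-donor-acceptor
CATION_PI_MAX_DIST = 6.0      # Å, cation group centroid to ring centroid
CATION_PI_MAX_TILT = 60.0     # degrees off the ring normal
REPULSIVE_MAX_DIST = 5.0      # Å, like-charge group centroids

#: Named side-chain groups (author atom names) used for centroid distances.
GROUP_ATOMS: dict[str, dict[str, tuple[str, ...]]] = {
    "guanidinium": {"ARG": ("CZ", "NH1", "NH2", "NE")},
    "ammonium": {"LYS": ("NZ",)},
    "carboxylate": {"GLU": ("CD", "OE1", "OE2"), "ASP": ("CG", "OD1", "OD2")},
    "phenol_ring": {"TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "aromatic_ring": {
        "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    },
}

#: Side-chain hydrogen-bond donors as (donor atom, antecedent atom) pairs,
#: and acceptors, by residue name.  Backbone N (antecedent CA) and backbone
#: O are handled for every residue.
SIDECHAIN_DONORS: dict[str, tuple[tuple[str, str], ...]] = {
    "SER": (("OG", "CB"),), "THR": (("OG1", "CB"),), "TYR": (("OH", "CZ"),),
    "CYS": (("SG", "CB"),), "ASN": (("ND2", "CG"),), "GLN": (("NE2", "CD"),),
    "LYS": (("NZ", "CE"),),
    "ARG": (("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")),
    "HIS": (("ND1", "CG"), ("NE2", "CD2")),
    "TRP": (("NE1", "CD1"),),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}

WATER_NAMES = {"HOH", "WAT", "DOD"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}


# ---------------------------------------------------------------------------
# structure container
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Column-oriented atom record of one model."""

    chain: list[str]
    resnum: np.ndarray
    resname: list[str]
    atomname: list[str]
    element: list[str]
    mass: np.ndarray
    xyz: np.ndarray
    occupancy: np.ndarray
    altloc: list[str]
    model_id: str = "1"
    is_hetero: np.ndarray | None = None

    def __post_init__(self):
        self.resnum = np.asarray(self.resnum, int)
        self.mass = np.asarray(self.mass, float)
        self.xyz = np.asarray(self.xyz, float)
        self.occupancy = np.asarray(self.occupancy, float)
        n = len(self.chain)
        if self.is_hetero is None:
            self.is_hetero = np.zeros(n, bool)
        if not (len(self.resnum) == len(self.resname) == len(self.atomname)
                == len(self.element) == len(self.mass) == n == len(self.xyz)):
            raise InputError("inconsistent atom column lengths")
        if not np.all(np.isfinite(self.xyz)):
            raise InputError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.chain)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([gemmi.Element(e).atomic_number for e in self.element], float)

    @property
    def masses(self) -> np.ndarray:
        return self.mass

    def subset(self, mask: np.ndarray) -> "StructureModel":
        idx = np.flatnonzero(mask)
        take = lambda seq: [seq[i] for i in idx]
        return StructureModel(
            chain=take(self.chain), resnum=self.resnum[idx],
            resname=take(self.resname), atomname=take(self.atomname),
            element=take(self.element), mass=self.mass[idx],
            xyz=self.xyz[idx], occupancy=self.occupancy[idx],
            altloc=take(self.altloc), model_id=self.model_id,
            is_hetero=self.is_hetero[idx],
        )

    def select(self, chain: str | None = None, resnums: Iterable[int] | None = None,
               atomnames: Iterable[str] | None = None) -> "StructureModel":
        mask = np.ones(len(self), bool)
        if chain is not None:
            mask &= np.array([c == chain for c in self.chain])
        if resnums is not None:
            wanted = set(int(r) for r in resnums)
            mask &= np.array([r in wanted for r in self.resnum])
        if atomnames is not None:
            names = set(atomnames)
            mask &= np.array([a in names for a in self.atomname])
        return self.subset(mask)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = replace(self)
        out.xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def mass_center(self) -> np.ndarray:
        return np.average(self.xyz, axis=0, weights=self.mass)

    def residue_atoms(self, chain: str, resnum: int) -> "StructureModel":
        sub = self.select(chain=chain, resnums=[resnum])
        if len(sub) == 0:
            raise InputError(f"no atoms for residue {chain}/{resnum}")
        return sub


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_structure(
    path: str | Path,
    chain: str | None = None,
    altloc_policy: str = "occupancy",
    keep_waters: bool = False,
    keep_hetero: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Keeps one conformer per atom: the highest-occupancy altloc under the
    default policy, or the first encountered under ``altloc_policy="first"``.
    Waters and other heteroatoms are dropped unless requested (they are
    never part of domain mass centers).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    chains = [ch.name for ch in model]
    if chain is not None and chain not in chains:
        raise InputError(f"chain {chain!r} not in {path.name}; available: {', '.join(chains)}")

    cols: dict[str, list] = {k: [] for k in
                             ("chain", "resnum", "resname", "atomname",
                              "element", "mass", "xyz", "occ", "altloc", "het")}
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            water = res.name in WATER_NAMES
            # standard amino acids count as protein even when a file marks
            # them HETATM (short synthetic chains, modified entities)
            hetero = res.het_flag == "H" and res.name not in STANDARD_AA
            if water and not keep_waters:
                continue
            if hetero and not water and not keep_hetero:
                continue
            # altloc resolution per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                elif altloc_policy == "occupancy" and atom.occ > prev.occ:
                    by_name[atom.name] = atom
            for name, atom in by_name.items():
                cols["chain"].append(ch.name)
                cols["resnum"].append(res.seqid.num)
                cols["resname"].append(res.name)
                cols["atomname"].append(name)
                cols["element"].append(atom.element.name)
                cols["mass"].append(atom.element.weight)
                cols["xyz"].append([atom.pos.x, atom.pos.y, atom.pos.z])
                cols["occ"].append(atom.occ)
                cols["altloc"].append(atom.altloc or "")
                cols["het"].append(hetero or water)
    if not cols["chain"]:
        raise InputError(f"{path}: no atoms selected (chain={chain!r})")
    return StructureModel(
        chain=cols["chain"], resnum=np.array(cols["resnum"]),
        resname=cols["resname"], atomname=cols["atomname"],
        element=cols["element"], mass=np.array(cols["mass"]),
        xyz=np.array(cols["xyz"]), occupancy=np.array(cols["occ"]),
        altloc=cols["altloc"], is_hetero=np.array(cols["het"], bool),
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a PDB file (via gemmi)."""
    # gemmi's add_residue/add_chain copy their argument, so each level must
    # be fully populated before being added to its parent
    order: list[tuple[str, int]] = []
    grouped: dict[tuple[str, int], list[int]] = {}
    for i in range(len(model)):
        key = (model.chain[i], int(model.resnum[i]))
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(i)

    st = gemmi.Structure()
    st.name = "glkit"
    md = gemmi.Model("1")
    current_chain: gemmi.Chain | None = None
    for cname, resnum in order:
        if current_chain is None or current_chain.name != cname:
            if current_chain is not None:
                md.add_chain(current_chain)
            current_chain = gemmi.Chain(cname)
        res = gemmi.Residue()
        idx0 = grouped[(cname, resnum)][0]
        res.name = model.resname[idx0]
        res.seqid = gemmi.SeqId(resnum, " ")
        res.het_flag = "H" if model.is_hetero[idx0] else "A"
        for i in grouped[(cname, resnum)]:
            atom = gemmi.Atom()
            atom.name = model.atomname[i]
            atom.element = gemmi.Element(model.element[i])
            atom.pos = gemmi.Position(*model.xyz[i])
            atom.occ = float(model.occupancy[i])
            res.add_atom(atom)
        current_chain.add_residue(res)
    if current_chain is not None:
        md.add_chain(current_chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# domain partition
# ---------------------------------------------------------------------------

@dataclass
class DomainPartition:
    """Residue-range assignment to the two domains, author numbering.

    ``ranges`` maps domain name -> list of (chain, first_resnum,
    last_resnum), inclusive.  Exactly the names {"large", "small"} are
    required; linker residues may be left unassigned.
    """

    ranges: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self):
        if set(self.ranges) != {"large", "small"}:
            raise PartitionError("partition must name exactly the domains 'large' and 'small'")
        seen: set[tuple[str, int]] = set()
        for name, rngs in self.ranges.items():
            if not rngs:
                raise PartitionError(f"domain {name!r} has no ranges")
            for chain, lo, hi in rngs:
                if hi < lo:
                    raise PartitionError(f"range {chain}:{lo}-{hi} is inverted")
                for r in range(lo, hi + 1):
                    if (chain, r) in seen:
                        raise PartitionError(f"residue {chain}/{r} assigned to both domains")
                    seen.add((chain, r))

    def mask(self, model: StructureModel, domain: str) -> np.ndarray:
        rngs = self.ranges[domain]
        mask = np.zeros(len(model), bool)
        for chain, lo, hi in rngs:
            mask |= np.array([c == chain and lo <= r <= hi
                              for c, r in zip(model.chain, model.resnum)])
        return mask & ~model.is_hetero

    def domain_of(self, chain: str, resnum: int) -> str | None:
        for name, rngs in self.ranges.items():
            for c, lo, hi in rngs:
                if c == chain and lo <= resnum <= hi:
                    return name
        return None

    def to_cfg(self) -> str:
        lines = ["# glkit domain partition (chain:first-last, author numbering)"]
        for name in ("large", "small"):
            spans = ", ".join(f"{c}:{lo}-{hi}" for c, lo, hi in self.ranges[name])
            lines.append(f"{name} = {spans}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_cfg(cls, text_or_path: str | Path) -> "DomainPartition":
        p = Path(text_or_path) if isinstance(text_or_path, Path) else None
        if p is None and isinstance(text_or_path, str) and "\n" not in text_or_path \
                and Path(text_or_path).exists():
            p = Path(text_or_path)
        text = p.read_text() if p is not None else str(text_or_path)
        ranges: dict[str, list[tuple[str, int, int]]] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, _, value = line.partition("=")
            name = name.strip()
            spans = []
            for item in value.split(","):
                item = item.strip()
                chain, _, span = item.partition(":")
                lo, _, hi = span.partition("-")
                spans.append((chain.strip(), int(lo), int(hi)))
            ranges[name] = spans
        return cls(ranges)


def default_tlgk_partition() -> DomainPartition:
    """Domain partition shipped for T. litoralis glucokinase, chain A.

    The small (lid) domain is the insertion in the large Rossmann-core
    domain; ranges were fixed once from the cluster-residue memberships of
    the two domains and are a configuration choice, not a fitted quantity.
    """
    cfg = Path(__file__).parent / "data" / "tlgk_domains.cfg"
    return DomainPartition.from_cfg(cfg.read_text())


# ---------------------------------------------------------------------------
# closure metrics
# ---------------------------------------------------------------------------

def domain_distance(model: StructureModel, partition: DomainPartition) -> float:
    """Distance (Å) between the mass-weighted centers of the two domains."""
    centers = []
    for name in ("large", "small"):
        sub = model.subset(partition.mask(model, name))
        if len(sub) == 0:
            raise PartitionError(f"domain {name!r} selects no atoms of this model")
        centers.append(sub.mass_center())
    return float(np.linalg.norm(centers[0] - centers[1]))


def superpose_kabsch(reference: np.ndarray, moving: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns (R, t, rmsd) with moving @ R.T + t ≈ reference and det(R) = +1
    (a proper rotation even for mirror-image inputs).
    """
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise InputError("paired (n,3) coordinate sets required")
    if len(ref) < 3:
        raise InputError("need at least 3 paired points")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    h = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise InputError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ref.mean(axis=0) - rot @ mov.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((mov @ rot.T + t - ref) ** 2, axis=1))))
    return rot, t, rmsd


def rotation_angle(rotation: np.ndarray) -> float:
    """Rotation angle (degrees) of a proper rotation matrix."""
    tr = float(np.trace(rotation))
    return math.degrees(math.acos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))


def rotation_axis(rotation: np.ndarray) -> np.ndarray:
    """Unit rotation axis of a proper rotation matrix (undefined sign at 0°)."""
    w, v = np.linalg.eig(rotation)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    n = np.linalg.norm(axis)
    return axis / n if n > 0 else np.array([0.0, 0.0, 1.0])


@dataclass
class RotationResult:
    angle_deg: float
    axis: np.ndarray
    screw_translation: float     # Å, translation component along the axis
    rmsd_large: float
    rmsd_small: float
    n_large: int
    n_small: int


def interdomain_rotation(
    model_ref: StructureModel,
    model_alt: StructureModel,
    partition: DomainPartition,
    atom_name: str = "CA",
) -> RotationResult:
    """Inter-domain rotation between two conformers of the same protein.

    Pairs Cα atoms by (chain, author residue number); superposes the
    alternate model on the reference via the large domain, then measures the
    residual rigid rotation of the small domain: θ = arccos((tr R − 1)/2).
    """
    pairs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in ("large", "small"):
        ref = model_ref.subset(partition.mask(model_ref, name)).select(atomnames=[atom_name])
        alt = model_alt.subset(partition.mask(model_alt, name)).select(atomnames=[atom_name])
        ref_keys = {(c, int(r)): i for i, (c, r) in enumerate(zip(ref.chain, ref.resnum))}
        alt_keys = {(c, int(r)): i for i, (c, r) in enumerate(zip(alt.chain, alt.resnum))}
        common = sorted(set(ref_keys) & set(alt_keys))
        if len(common) < 10:
            raise InputError(f"only {len(common)} common {atom_name} atoms in the "
                             f"{name} domain; need >=10")
        pairs[name] = (
            ref.xyz[[ref_keys[k] for k in common]],
            alt.xyz[[alt_keys[k] for k in common]],
        )

    rot_l, t_l, rmsd_l = superpose_kabsch(pairs["large"][0], pairs["large"][1])
    small_alt_aligned = pairs["small"][1] @ rot_l.T + t_l
    rot_s, t_s, rmsd_s = superpose_kabsch(pairs["small"][0], small_alt_aligned)
    axis = rotation_axis(rot_s)
    # screw decomposition: translation of the small-domain centroid along the axis
    centroid = small_alt_aligned.mean(axis=0)
    shift = (rot_s @ centroid + t_s) - centroid
    return RotationResult(
        angle_deg=rotation_angle(rot_s),
        axis=axis,
        screw_translation=float(np.dot(shift, axis)),
        rmsd_large=rmsd_l,
        rmsd_small=rmsd_s,
        n_large=len(pairs["large"][0]),
        n_small=len(pairs["small"][0]),
    )


# ---------------------------------------------------------------------------
# groups and interactions
# ---------------------------------------------------------------------------

def _group_coords(model: StructureModel, chain: str, resnum: int,
                  group: str | Sequence[str]) -> np.ndarray:
    res = model.residue_atoms(chain, resnum)
    resname = res.resname[0]
    if isinstance(group, str):
        table = GROUP_ATOMS.get(group)
        if table is None:
            raise InputError(f"unknown group name {group!r}; known: {sorted(GROUP_ATOMS)}")
        names = table.get(resname)
        if names is None:
            raise InputError(f"group {group!r} is not defined for residue {resname}")
    else:
        names = tuple(group)
    have = {a: i for i, a in enumerate(res.atomname)}
    missing = [n for n in names if n not in have]
    if missing:
        raise InputError(f"residue {chain}/{resnum} ({resname}) lacks atoms: {', '.join(missing)}")
    return res.xyz[[have[n] for n in names]]


def group_centroid(model: StructureModel, chain: str, resnum: int,
                   group: str | Sequence[str]) -> np.ndarray:
    return _group_coords(model, chain, resnum, group).mean(axis=0)


def group_distance(model: StructureModel,
                   residue_a: tuple[str, int], group_a: str | Sequence[str],
                   residue_b: tuple[str, int], group_b: str | Sequence[str]) -> float:
    """Distance (Å) between the centroids of two named side-chain groups
    (single-atom groups degenerate to a plain atom distance)."""
    ca = group_centroid(model, *residue_a, group_a)
    cb = group_centroid(model, *residue_b, group_b)
    return float(np.linalg.norm(ca - cb))


@dataclass(frozen=True)
class InteractionRecord:
    kind: str                      # hbond | cation_pi | repulsive_pair
    chain_a: str
    resnum_a: int
    resname_a: str
    domain_a: str
    chain_b: str
    resnum_b: int
    resname_b: str
    domain_b: str
    atoms_a: tuple[str, ...]
    atoms_b: tuple[str, ...]
    distance: float
    qualifier: float | None = None  # angle in degrees where applicable


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _charged_groups(model: StructureModel, mask: np.ndarray, domain: str):
    """(sign, record stub, centroid) for Lys/Arg (+) and Glu/Asp (−)."""
    out = []
    sub = model.subset(mask)
    for chain, resnum in sorted({(c, int(r)) for c, r in zip(sub.chain, sub.resnum)}):
        res = model.residue_atoms(chain, resnum)
        resname = res.resname[0]
        try:
            if resname == "LYS":
                out.append((+1, chain, resnum, resname, domain, ("NZ",),
                            group_centroid(model, chain, resnum, "ammonium")))
            elif resname == "ARG":
                out.append((+1, chain, resnum, resname, domain,
                            GROUP_ATOMS["guanidinium"]["ARG"],
                            group_centroid(model, chain, resnum, "guanidinium")))
            elif resname in ("GLU", "ASP"):
                out.append((-1, chain, resnum, resname, domain,
                            GROUP_ATOMS["carboxylate"][resname],
                            group_centroid(model, chain, resnum, "carboxylate")))
        except InputError:
            continue  # truncated side chain: skip, never guess
    return out


def detect_interactions(model: StructureModel, partition: DomainPartition,
                        kinds: Sequence[str] = ("hbond", "cation_pi", "repulsive_pair"),
                        ) -> list[InteractionRecord]:
    """Enumerate inter-domain interactions under the module's geometric
    criteria.  Only residue pairs assigned to *different* domains are
    reported; ordering is deterministic (small-domain residue first, then
    residue numbers, then kind)."""
    masks = {name: partition.mask(model, name) for name in ("large", "small")}
    records: list[InteractionRecord] = []

    def domain_and_res(mask, domain):
        sub = model.subset(mask)
        return sorted({(c, int(r)) for c, r in zip(sub.chain, sub.resnum)})

    if "hbond" in kinds:
        records += _detect_hbonds(model, partition, masks)
    if "cation_pi" in kinds:
        records += _detect_cation_pi(model, partition, masks)
    if "repulsive_pair" in kinds:
        records += _detect_repulsive(model, partition, masks)
    records.sort(key=lambda r: (r.resnum_a, r.resnum_b, r.kind, r.atoms_a, r.atoms_b))
    return records


def _donors_acceptors(model: StructureModel, mask: np.ndarray):
    donors, acceptors = [], []
    sub = model.subset(mask)
    for chain, resnum in sorted({(c, int(r)) for c, r in zip(sub.chain, sub.resnum)}):
        res = model.residue_atoms(chain, resnum)
        resname = res.resname[0]
        have = {a: i for i, a in enumerate(res.atomname)}
        if "N" in have and "CA" in have:
            donors.append((chain, resnum, resname, "N", res.xyz[have["N"]], res.xyz[have["CA"]]))
        for donor, antecedent in SIDECHAIN_DONORS.get(resname, ()):
            if donor in have and antecedent in have:
                donors.append((chain, resnum, resname, donor,
                               res.xyz[have[donor]], res.xyz[have[antecedent]]))
        if "O" in have:
            acceptors.append((chain, resnum, resname, "O", res.xyz[have["O"]]))
        for acc in SIDECHAIN_ACCEPTORS.get(resname, ()):
            if acc in have:
                acceptors.append((chain, resnum, resname, acc, res.xyz[have[acc]]))
    return donors, acceptors


def _detect_hbonds(model, partition, masks) -> list[InteractionRecord]:
    records = []
    don = {d: _donors_acceptors(model, masks[d])[0] for d in masks}
    acc = {d: _donors_acceptors(model, masks[d])[1] for d in masks}
    for d_dom, a_dom in (("small", "large"), ("large", "small")):
        for chain_d, res_d, name_d, atom_d, pos_d, pos_ante in don[d_dom]:
            for chain_a, res_a, name_a, atom_a, pos_a in acc[a_dom]:
                dist = float(np.linalg.norm(pos_d - pos_a))
                if dist > HBOND_MAX_DIST:
                    continue
                v1 = pos_ante - pos_d
                v2 = pos_a - pos_d
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle < HBOND_MIN_ANGLE:
                    continue
                first_small = d_dom == "small"
                rec = InteractionRecord(
                    kind="hbond",
                    chain_a=chain_d if first_small else chain_a,
                    resnum_a=res_d if first_small else res_a,
                    resname_a=name_d if first_small else name_a,
                    domain_a="small",
                    chain_b=chain_a if first_small else chain_d,
                    resnum_b=res_a if first_small else res_d,
                    resname_b=name_a if first_small else name_d,
                    domain_b="large",
                    atoms_a=(atom_d,) if first_small else (atom_a,),
                    atoms_b=(atom_a,) if first_small else (atom_d,),
                    distance=dist, qualifier=angle)
                records.append(rec)
    return records


def _detect_cation_pi(model, partition, masks) -> list[InteractionRecord]:
    records = []
    cations = {d: [g for g in _charged_groups(model, masks[d], d) if g[0] > 0] for d in masks}
    rings = {d: [] for d in masks}
    for d, mask in masks.items():
        sub = model.subset(mask)
        for chain, resnum in sorted({(c, int(r)) for c, r in zip(sub.chain, sub.resnum)}):
            res = model.residue_atoms(chain, resnum)
            resname = res.resname[0]
            names = GROUP_ATOMS["aromatic_ring"].get(resname)
            if names is None:
                continue
            try:
                coords = _group_coords(model, chain, resnum, names)
            except InputError:
                continue
            rings[d].append((chain, resnum, resname, names,
                             coords.mean(axis=0), _ring_normal(coords)))
    for c_dom, r_dom in (("small", "large"), ("large", "small")):
        for _, chain_c, res_c, name_c, dom_c, atoms_c, cen_c in cations[c_dom]:
            for chain_r, res_r, name_r, atoms_r, cen_r, normal in rings[r_dom]:
                vec = cen_c - cen_r
                dist = float(np.linalg.norm(vec))
                if dist > CATION_PI_MAX_DIST or dist == 0.0:
                    continue
                tilt = math.degrees(math.acos(np.clip(abs(np.dot(vec / dist, normal)), -1.0, 1.0)))
                if tilt > CATION_PI_MAX_TILT:
                    continue
                first_small = c_dom == "small"
                records.append(InteractionRecord(
                    kind="cation_pi",
                    chain_a=chain_c if first_small else chain_r,
                    resnum_a=res_c if first_small else res_r,
                    resname_a=name_c if first_small else name_r,
                    domain_a="small",
                    chain_b=chain_r if first_small else chain_c,
                    resnum_b=res_r if first_small else res_c,
                    resname_b=name_r if first_small else name_c,
                    domain_b="large",
                    atoms_a=tuple(atoms_c) if first_small else tuple(atoms_r),
                    atoms_b=tuple(atoms_r) if first_small else tuple(atoms_c),
                    distance=dist, qualifier=tilt))
    return records


def _detect_repulsive(model, partition, masks) -> list[InteractionRecord]:
    records = []
    groups = {d: _charged_groups(model, masks[d], d) for d in masks}
    for sign_s, chain_s, res_s, name_s, dom_s, atoms_s, cen_s in groups["small"]:
        for sign_l, chain_l, res_l, name_l, dom_l, atoms_l, cen_l in groups["large"]:
            if sign_s != sign_l:
                continue
            dist = float(np.linalg.norm(cen_s - cen_l))
            if dist > REPULSIVE_MAX_DIST:
                continue
            records.append(InteractionRecord(
                kind="repulsive_pair",
                chain_a=chain_s, resnum_a=res_s, resname_a=name_s, domain_a="small",
                chain_b=chain_l, resnum_b=res_l, resname_b=name_l, domain_b="large",
                atoms_a=tuple(atoms_s), atoms_b=tuple(atoms_l),
                distance=dist, qualifier=None))
    return records


def interactions_to_tsv(records: Sequence[InteractionRecord], path: str | Path) -> None:
    lines = ["kind\tres_a\tres_b\tdistance\tqualifier"]
    for r in records:
        qual = f"{r.qualifier:.2f}" if r.qualifier is not None else ""
        lines.append(f"{r.kind}\t{r.chain_a}/{r.resname_a}{r.resnum_a}({r.domain_a})"
                     f"\t{r.chain_b}/{r.resname_b}{r.resnum_b}({r.domain_b})"
                     f"\t{r.distance:.3f}\t{qual}")
    Path(path).write_text("\n".join(lines) + "\n")
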