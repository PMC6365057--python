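"""GPCR structural-compatibility analysis: TM superposition and contacts.

For chimeric receptor design, two questions are asked of a receptor pair in
matched activation states: (1) how similar are their transmembrane (TM)
helix bundles — measured as the CA RMSD after least-squares rigid (Kabsch)
superposition over paired TM1–7 residues — and (2) how similar are the
non-covalent contact networks stabilising the bundle — measured as the
number and helix-pair distribution of inter-segment residue contacts, where
a contact is any heavy-atom pair within the sum of the van der Waals radii
plus a tolerance (0.5 Å by default, the criterion popularised by contact
atlases).

Segment definitions (TM1–TM7, H8 residue ranges per chain) are supplied as
annotation config, not derived from the coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "HelixAnnotation",
    "ContactNetwork",
    "SuperpositionResult",
    "VDW_RADII",
    "TM_SEGMENTS",
    "read_structure",
    "write_pdb",
    "load_annotations",
    "superpose",
    "pair_residues",
    "contact_network",
    "interhelical_counts",
    "contact_distribution",
]

TM_SEGMENTS = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7")
ALL_SEGMENTS = TM_SEGMENTS + ("H8",)

# Bondi van der Waals radii, Å
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70


@dataclass
class StructureModel:
    """Atomic coordinates as a tidy table.

    ``atoms`` columns: ``chain, resnum, icode, resname, atom_name, element,
    x, y, z, occupancy``. Heavy atoms only, altloc already resolved.
    """

    atoms: pd.DataFrame
    source_id: str = ""

    def __post_init__(self):
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def ca_coords(self, resnums) -> np.ndarray:
        """CA coordinates for the given residue numbers, in their order."""
        ca = self.atoms[self.atoms["atom_name"] == "CA"].set_index("resnum")
        out = []
        for r in resnums:
            if r not in ca.index:
                raise KeyError(f"no CA atom for residue {r}")
            row = ca.loc[r]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            out.append([row["x"], row["y"], row["z"]])
        return np.asarray(out, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        atoms = self.atoms.copy()
        xyz = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        atoms[["x", "y", "z"]] = xyz
        return StructureModel(atoms=atoms, source_id=self.source_id)


@dataclass
class HelixAnnotation:
    """Per-segment residue ranges (inclusive) on one chain.

    ``segments`` maps a segment name (TM1..TM7, H8) to a list of
    ``(first, last)`` residue-number ranges; ``generic`` optionally maps a
    residue number to its generic (structure-based) position label.
    """

    chain: str
    segments: dict
    generic: dict | None = None

    def __post_init__(self):
        seen = {}
        for seg, ranges in self.segments.items():
            for lo, hi in ranges:
                if hi < lo:
                    raise ValueError(f"{seg}: empty range ({lo}, {hi})")
                for r in range(int(lo), int(hi) + 1):
                    if r in seen:
                        raise ValueError(
                            f"residue {r} assigned to both {seen[r]} and {seg}"
                        )
                    seen[r] = seg
        self._segment_of = seen

    def residues(self, segment: str) -> list:
        return [
            r
            for lo, hi in self.segments[segment]
            for r in range(int(lo), int(hi) + 1)
        ]

    def segment_of(self, resnum: int):
        return self._segment_of.get(resnum)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # applied to model B coordinates
    translation: np.ndarray
    rmsd: float
    n_pairs: int


@dataclass
class ContactNetwork:
    """Inter-segment residue contacts with minimal atom distances."""

    contacts: pd.DataFrame  # res_a, seg_a, res_b, seg_b, min_dist
    source_id: str = ""


def read_structure(path, chain: str | None = None, exclude_ranges=None) -> StructureModel:
    """Parse a PDB/mmCIF file into a StructureModel.

    Keeps the first model, the requested chain (default: first chain),
    altloc '' or 'A' only, heavy atoms only, and drops waters. Residue
    ranges in ``exclude_ranges`` (inclusive ``(first, last)`` pairs, e.g.
    fusion-construct residues) are removed.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        chain = names[0]
    if chain not in names:
        raise ValueError(f"{path}: chain {chain!r} not found (have {names})")
    exclude_ranges = exclude_ranges or []
    rows = []
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.is_water():
                continue
            rn = res.seqid.num
            if any(lo <= rn <= hi for lo, hi in exclude_ranges):
                continue
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.altloc not in ("\0", "", "A"):
                    continue
                rows.append(
                    (
                        ch.name,
                        rn,
                        res.seqid.icode.strip(),
                        res.name,
                        atom.name,
                        atom.element.name.upper(),
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.occ,
                    )
                )
    if not rows:
        raise ValueError(f"{path}: chain {chain!r} has no usable atoms")
    atoms = pd.DataFrame(
        rows,
        columns=[
            "chain", "resnum", "icode", "resname", "atom_name", "element",
            "x", "y", "z", "occupancy",
        ],
    )
    return StructureModel(atoms=atoms, source_id=Path(path).stem)


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel to a minimal PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.source_id or "model"
    md = gemmi.Model("1")
    for chain_name, chain_df in model.atoms.groupby("chain", sort=False):
        ch = gemmi.Chain(str(chain_name))
        for (rn, icode, resname), res_df in chain_df.groupby(
            ["resnum", "icode", "resname"], sort=False
        ):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(rn), icode if icode else " ")
            for _, a in res_df.iterrows():
                atom = gemmi.Atom()
                atom.name = str(a["atom_name"])
                atom.element = gemmi.Element(str(a["element"]))
                atom.pos = gemmi.Position(a["x"], a["y"], a["z"])
                atom.occ = float(a["occupancy"])
                res.add_atom(atom)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def load_annotations(path) -> dict:
    """Load a YAML annotation config: structure key → HelixAnnotation (+io).

    Expected layout::

        structures:
          1u19:
            chain: A
            exclude: [[1001, 1100]]
            segments: {TM1: [[34, 64]], ...}
            generic: {34: "1x30", ...}   # optional
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for key, entry in raw["structures"].items():
        segments = {
            seg: [tuple(r) for r in ranges]
            for seg, ranges in entry["segments"].items()
        }
        generic = entry.get("generic")
        if generic is not None:
            generic = {int(k): str(v) for k, v in generic.items()}
        out[key] = {
            "chain": entry.get("chain", "A"),
            "exclude": [tuple(r) for r in entry.get("exclude", [])],
            "annotation": HelixAnnotation(
                chain=entry.get("chain", "A"), segments=segments, generic=generic
            ),
        }
    return out


def pair_residues(
    annot_a: HelixAnnotation,
    annot_b: HelixAnnotation,
    mode: str = "trim",
    segments=TM_SEGMENTS,
) -> list:
    """Residue pairing between two annotated structures.

    ``mode="generic"`` pairs residues sharing a generic position label
    (intersection of the mapped labels, per segment). ``mode="trim"`` pairs
    segment residues index-by-index after trimming the longer segment to the
    shorter's length symmetrically from both ends; when the excess is odd
    the extra residue is dropped from the C-terminal end.
    """
    pairs = []
    for seg in segments:
        if seg not in annot_a.segments or seg not in annot_b.segments:
            continue
        ra = annot_a.residues(seg)
        rb = annot_b.residues(seg)
        if mode == "trim":
            n = min(len(ra), len(rb))
            ea, eb = len(ra) - n, len(rb) - n
            ra = ra[ea // 2 : len(ra) - (ea - ea // 2)]
            rb = rb[eb // 2 : len(rb) - (eb - eb // 2)]
            pairs.extend(zip(ra, rb))
        elif mode == "generic":
            if annot_a.generic is None or annot_b.generic is None:
                raise ValueError("generic mode needs generic-number mappings")
            ga = {annot_a.generic[r]: r for r in ra if r in annot_a.generic}
            gb = {annot_b.generic[r]: r for r in rb if r in annot_b.generic}
            for label in sorted(ga.keys() & gb.keys()):
                pairs.append((ga[label], gb[label]))
        else:
            raise ValueError(f"unknown pairing mode {mode!r}")
    if not pairs:
        raise ValueError("empty residue pairing")
    return pairs


def superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    pairing,
) -> SuperpositionResult:
    """Least-squares rigid (Kabsch) superposition of paired CA atoms.

    ``pairing`` is a sequence of ``(resnum_a, resnum_b)`` pairs; the CA atom
    of each residue is used, no outlier pruning. The returned transform maps
    model B coordinates onto model A; RMSD is over all pairs.
    """
    pairing = list(pairing)
    if len(pairing) < 3:
        raise ValueError("need at least 3 residue pairs to superpose")
    pa = model_a.ca_coords([p[0] for p in pairing])
    pb = model_b.ca_coords([p[1] for p in pairing])
    ca_mean, cb_mean = pa.mean(axis=0), pb.mean(axis=0)
    a_c, b_c = pa - ca_mean, pb - cb_mean
    if np.linalg.matrix_rank(np.vstack([a_c, b_c])) < 2:
        raise ValueError("degenerate (collinear) point sets")
    rot, _ = Rotation.align_vectors(a_c, b_c)
    aligned = rot.apply(b_c)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - a_c) ** 2, axis=1))))
    rotation = rot.as_matrix()
    translation = ca_mean - rotation @ cb_mean
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_pairs=len(pairing)
    )


def _vdw(element: str) -> float:
    el = element.upper()
    if el not in VDW_RADII:
        warnings.warn(f"unknown element {element!r}; using default vdW radius")
        return DEFAULT_VDW
    return VDW_RADII[el]


def contact_network(
    model: StructureModel,
    annotation: HelixAnnotation,
    tolerance: float = 0.5,
    radii: dict | None = None,
) -> ContactNetwork:
    """Inter-segment residue contacts under the vdW-sum + tolerance rule.

    Two residues assigned to *different* segments are in contact when any
    heavy-atom pair satisfies ``d <= r_vdw(i) + r_vdw(j) + tolerance``. Each
    unordered residue pair is reported once with its minimal atom distance.
    Residues with missing heavy atoms participate with the atoms present.
    """
    radii = radii or VDW_RADII
    seg = model.atoms["resnum"].map(annotation.segment_of)
    atoms = model.atoms[seg.notna()].copy()
    atoms["segment"] = seg[seg.notna()]
    if atoms.empty:
        raise ValueError("no atoms fall inside the annotated segments")
    xyz = atoms[["x", "y", "z"]].to_numpy(dtype=float)
    rad = np.array([radii.get(e.upper(), _vdw(e)) for e in atoms["element"]])
    resnum = atoms["resnum"].to_numpy()
    segment = atoms["segment"].to_numpy()

    tree = cKDTree(xyz)
    max_cut = 2 * rad.max() + tolerance
    candidate = tree.query_pairs(max_cut, output_type="ndarray")
    if len(candidate):
        i, j = candidate[:, 0], candidate[:, 1]
        d = np.linalg.norm(xyz[i] - xyz[j], axis=1)
        ok = (d <= rad[i] + rad[j] + tolerance) & (segment[i] != segment[j])
        i, j, d = i[ok], j[ok], d[ok]
    else:
        i = j = d = np.array([])

    best = {}
    for ii, jj, dd in zip(i, j, d):
        ra, rb = int(resnum[ii]), int(resnum[jj])
        sa, sb = segment[ii], segment[jj]
        key = (ra, rb) if ra < rb else (rb, ra)
        if key not in best or dd < best[key][2]:
            segs = (sa, sb) if ra < rb else (sb, sa)
            best[key] = (segs[0], segs[1], float(dd))
    rows = [
        (ra, v[0], rb, v[1], v[2]) for (ra, rb), v in sorted(best.items())
    ]
    df = pd.DataFrame(rows, columns=["res_a", "seg_a", "res_b", "seg_b", "min_dist"])
    return ContactNetwork(contacts=df, source_id=model.source_id)


def interhelical_counts(network: ContactNetwork) -> dict:
    """Contact counts keyed by unordered segment pair, plus ``'total'``."""
    counts = {}
    for _, row in network.contacts.iterrows():
        key = tuple(sorted((row["seg_a"], row["seg_b"])))
        counts[key] = counts.get(key, 0) + 1
    counts["total"] = int(sum(v for k, v in counts.items() if k != "total"))
    return counts


def contact_distribution(counts: dict, pair_set=None):
    """Fraction of contacts per segment pair (sums to 1).

    With ``pair_set`` (an iterable of segment pairs), also returns the
    summed fraction over that set — e.g. the sequence-adjacent helix pairs
    TM1–TM2 … TM6–TM7.
    """
    total = counts.get("total", 0)
    if total <= 0:
        raise ValueError("zero total contacts")
    fractions = {
        k: v / total for k, v in counts.items() if k != "total"
    }
    if pair_set is None:
        return fractions
    wanted = {tuple(sorted(p)) for p in pair_set}
    summed = sum(f for k, f in fractions.items() if k in wanted)
    return fractions, summed
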