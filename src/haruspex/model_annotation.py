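"""Atomic-model parsing and per-residue secondary-structure labels.

Residues are labeled with one of four classes — ``helix``, ``sheet``,
``nucleotide``, ``unassigned`` — from three sources, merged in this order:

1. nucleotide residues are always ``nucleotide``;
2. author HELIX/SHEET (or ``struct_conf``/``struct_sheet_range``) records;
3. hydrogen-bond detection: a variant of the Kabsch–Sander (DSSP) analysis in
   which strand direction is ignored — parallel and antiparallel bridge
   patterns both simply mark residues as ``sheet``;
4. a torsion-angle extension: unassigned residues bordering a helix or sheet
   are absorbed when their (phi, psi) pair falls in the matching Ramachandran
   window.

Author records win over detected labels where they disagree, since deposited
models are treated as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._geom import dihedral

__all__ = [
    "CLASSES",
    "Residue",
    "Chain",
    "AuthorSS",
    "StructuralModel",
    "ResidueLabels",
    "ModelFormatError",
    "EmptyModelError",
    "read_model",
    "hbond_energy",
    "assign_secondary_structure",
    "extend_by_ramachandran",
    "NO_BOND",
    "HBOND_CUTOFF",
    "HELIX_PHI_WINDOW",
    "HELIX_PSI_WINDOW",
    "SHEET_PHI_WINDOW",
    "SHEET_PSI_WINDOWS",
]

#: Class names in channel order used throughout the package.
CLASSES = ("helix", "sheet", "nucleotide", "unassigned")

#: Kabsch–Sander electrostatic H-bond energy threshold (kcal/mol).
HBOND_CUTOFF = -0.5
#: Sentinel energy meaning "no hydrogen bond possible" (never below cutoff).
NO_BOND = 0.0

_KS_Q = 0.084 * 332.0  # kcal*A/mol, Kabsch-Sander coupling constant
_MIN_DIST = 0.5        # clash guard: distances below this yield no bond

# Ramachandran windows for the torsion extension, degrees.
HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-80.0, -5.0)
SHEET_PHI_WINDOW = (-180.0, -45.0)
SHEET_PSI_WINDOWS = ((90.0, 180.0), (-180.0, -150.0))

_AA_BACKBONE = ("N", "CA", "C", "O")
_NUC_BACKBONE = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")


class ModelFormatError(ValueError):
    """Raised for unparseable model files."""


class EmptyModelError(ValueError):
    """Raised when a model contains no polymer residues."""


@dataclass
class Residue:
    chain_id: str
    seqid: int
    icode: str
    name: str
    kind: str  # "aa" | "nuc" | "other"
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seqid, self.icode)

    def backbone_atoms(self) -> List[np.ndarray]:
        names = _AA_BACKBONE if self.kind == "aa" else (
            _NUC_BACKBONE if self.kind == "nuc" else ())
        return [self.atoms[n] for n in names if n in self.atoms]


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)


@dataclass
class AuthorSS:
    chain_id: str
    start: Tuple[int, str]  # (seqid, icode)
    end: Tuple[int, str]
    ss_class: str  # "helix" | "sheet"


@dataclass
class StructuralModel:
    chains: List[Chain] = field(default_factory=list)
    author_ss: List[AuthorSS] = field(default_factory=list)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def polymer_residues(self) -> Iterator[Residue]:
        for res in self.residues():
            if res.kind in ("aa", "nuc"):
                yield res

    def all_atom_coords(self) -> np.ndarray:
        coords = [xyz for res in self.residues() for xyz in res.atoms.values()]
        return np.array(coords) if coords else np.empty((0, 3))


class ResidueLabels:
    """Mapping residue key -> class name; unknown keys read as unassigned."""

    def __init__(self, labels: Optional[Dict[Tuple[str, int, str], str]] = None):
        self._labels: Dict[Tuple[str, int, str], str] = dict(labels or {})

    def get(self, res: Residue) -> str:
        return self._labels.get(res.key, "unassigned")

    def get_key(self, key: Tuple[str, int, str]) -> str:
        return self._labels.get(key, "unassigned")

    def set(self, res: Residue, ss_class: str) -> None:
        if ss_class not in CLASSES:
            raise ValueError(f"unknown class {ss_class!r}")
        self._labels[res.key] = ss_class

    def copy(self) -> "ResidueLabels":
        return ResidueLabels(self._labels)

    def counts(self) -> Dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for v in self._labels.values():
            out[v] += 1
        return out

    def __len__(self) -> int:
        return len(self._labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, ResidueLabels) and self._labels == other._labels


# ---------------------------------------------------------------------------
# model reading

def _normalize_atom_name(name: str) -> str:
    return name.strip().replace("*", "'")


def _residue_kind(name: str, atoms: Dict[str, np.ndarray]) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "aa"
        if info.is_nucleic_acid():
            return "nuc"
        if info.is_water():
            return "other"
    # fallback for non-tabulated residues: decide from backbone atom names
    if {"N", "CA", "C"} <= atoms.keys():
        return "aa"
    if {"C4'", "C3'"} <= atoms.keys() or "P" in atoms:
        return "nuc"
    return "other"


def _pick_altlocs(raw_atoms: List[Tuple[str, str, float, np.ndarray]]) -> Dict[str, np.ndarray]:
    """Resolve alternate locations to the highest-occupancy copy (ties: first)."""
    best: Dict[str, Tuple[float, int, np.ndarray]] = {}
    for order, (name, _alt, occ, xyz) in enumerate(raw_atoms):
        cur = best.get(name)
        if cur is None or occ > cur[0]:
            best[name] = (occ, order, xyz)
    return {name: xyz for name, (_occ, _order, xyz) in best.items()}


def _from_gemmi(st: gemmi.Structure) -> StructuralModel:
    model = StructuralModel()
    if len(st) == 0:
        raise EmptyModelError("structure contains no models")
    gmodel = st[0]
    for gchain in gmodel:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            raw = [(_normalize_atom_name(a.name), a.altloc, float(a.occ),
                    np.array([a.pos.x, a.pos.y, a.pos.z])) for a in gres]
            atoms = _pick_altlocs(raw)
            icode = gres.seqid.icode.strip()
            chain.residues.append(Residue(
                chain_id=gchain.name, seqid=gres.seqid.num, icode=icode,
                name=gres.name, kind=_residue_kind(gres.name, atoms), atoms=atoms))
        chain.residues.sort(key=lambda r: (r.seqid, r.icode))
        if chain.residues:
            model.chains.append(chain)
    for hel in st.helices:
        model.author_ss.append(AuthorSS(
            chain_id=hel.start.chain_name,
            start=(hel.start.res_id.seqid.num, hel.start.res_id.seqid.icode.strip()),
            end=(hel.end.res_id.seqid.num, hel.end.res_id.seqid.icode.strip()),
            ss_class="helix"))
    for sheet in st.sheets:
        for strand in sheet.strands:
            model.author_ss.append(AuthorSS(
                chain_id=strand.start.chain_name,
                start=(strand.start.res_id.seqid.num, strand.start.res_id.seqid.icode.strip()),
                end=(strand.end.res_id.seqid.num, strand.end.res_id.seqid.icode.strip()),
                ss_class="sheet"))
    return model


def _text(el, tag: str) -> Optional[str]:
    for child in el:
        if child.tag.rsplit("}", 1)[-1] == tag:
            return child.text
    return None


def _from_pdbml(path: str) -> StructuralModel:
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ModelFormatError(f"cannot parse PDBML file {path!r}: {exc}") from exc
    root = tree.getroot()
    per_res: Dict[Tuple[str, int, str], List[Tuple[str, str, float, np.ndarray]]] = {}
    res_name: Dict[Tuple[str, int, str], str] = {}
    order: List[Tuple[str, int, str]] = []
    for el in root.iter():
        if el.tag.rsplit("}", 1)[-1] != "atom_site":
            continue
        model_num = _text(el, "pdbx_PDB_model_num")
        if model_num not in (None, "1"):
            continue
        chain = _text(el, "auth_asym_id") or _text(el, "label_asym_id") or "A"
        seq_s = _text(el, "auth_seq_id") or _text(el, "label_seq_id")
        if seq_s is None:
            continue
        icode = (_text(el, "pdbx_PDB_ins_code") or "").strip()
        name = _normalize_atom_name(_text(el, "label_atom_id") or "")
        alt = (_text(el, "label_alt_id") or "").strip()
        occ = float(_text(el, "occupancy") or 1.0)
        xyz = np.array([float(_text(el, "Cartn_x")), float(_text(el, "Cartn_y")),
                        float(_text(el, "Cartn_z"))])
        key = (chain, int(seq_s), icode)
        if key not in per_res:
            per_res[key] = []
            order.append(key)
            res_name[key] = _text(el, "label_comp_id") or "UNK"
        per_res[key].append((name, alt, occ, xyz))
    model = StructuralModel()
    chains: Dict[str, Chain] = {}
    for key in order:
        cid, seq, icode = key
        atoms = _pick_altlocs(per_res[key])
        chain = chains.setdefault(cid, Chain(chain_id=cid))
        chain.residues.append(Residue(chain_id=cid, seqid=seq, icode=icode,
                                      name=res_name[key],
                                      kind=_residue_kind(res_name[key], atoms),
                                      atoms=atoms))
    for chain in chains.values():
        chain.residues.sort(key=lambda r: (r.seqid, r.icode))
        model.chains.append(chain)
    for el in root.iter():
        short = el.tag.rsplit("}", 1)[-1]
        if short == "struct_conf":
            conf_type = (_text(el, "conf_type_id") or "")
            if not conf_type.upper().startswith("HELX"):
                continue
            model.author_ss.append(AuthorSS(
                chain_id=_text(el, "beg_auth_asym_id") or _text(el, "beg_label_asym_id") or "A",
                start=(int(_text(el, "beg_auth_seq_id") or _text(el, "beg_label_seq_id")), ""),
                end=(int(_text(el, "end_auth_seq_id") or _text(el, "end_label_seq_id")), ""),
                ss_class="helix"))
        elif short == "struct_sheet_range":
            model.author_ss.append(AuthorSS(
                chain_id=_text(el, "beg_auth_asym_id") or _text(el, "beg_label_asym_id") or "A",
                start=(int(_text(el, "beg_auth_seq_id") or _text(el, "beg_label_seq_id")), ""),
                end=(int(_text(el, "end_auth_seq_id") or _text(el, "end_label_seq_id")), ""),
                ss_class="sheet"))
    return model


def read_model(path: str) -> StructuralModel:
    """Read an atomic model from PDB, mmCIF, or PDBML.

    All residues (polymer and not) are retained — the 5 A exclusion rule in
    voxel labeling considers every model atom — but a model with zero polymer
    residues raises :class:`EmptyModelError`.
    """
    p = str(path)
    lower = p.lower()
    if lower.endswith((".xml", ".pdbml", ".xml.gz")):
        model = _from_pdbml(p)
    else:
        try:
            st = gemmi.read_structure(p)
        except (RuntimeError, ValueError, OSError) as exc:
            raise ModelFormatError(f"cannot parse model file {p!r}: {exc}") from exc
        model = _from_gemmi(st)
    if not any(True for _ in model.polymer_residues()):
        raise EmptyModelError(f"model {p!r} contains no polymer residues")
    return model


# ---------------------------------------------------------------------------
# hydrogen bonds

def _amide_hydrogen(donor: Residue, donor_prev: Residue) -> Optional[np.ndarray]:
    if "N" not in donor.atoms or "C" not in donor_prev.atoms or "O" not in donor_prev.atoms:
        return None
    co = donor_prev.atoms["C"] - donor_prev.atoms["O"]
    n = np.linalg.norm(co)
    if n == 0:
        return None
    # DSSP convention: N-H parallel to the preceding C=O bond, 1.0 A long
    return donor.atoms["N"] + co / n


def hbond_energy(donor: Residue, acceptor: Residue,
                 donor_prev: Optional[Residue] = None) -> float:
    """Kabsch–Sander electrostatic N-H...O=C energy in kcal/mol.

    ``donor`` contributes N-H (H is built from the preceding residue's C=O
    direction), ``acceptor`` contributes C=O. Returns :data:`NO_BOND` (0.0)
    when the bond cannot be formed: proline donor, missing atoms, no
    preceding residue, or clashing geometry.
    """
    if donor.name.upper() == "PRO":
        return NO_BOND
    if donor_prev is None:
        return NO_BOND
    if "N" not in donor.atoms or "C" not in acceptor.atoms or "O" not in acceptor.atoms:
        return NO_BOND
    h = _amide_hydrogen(donor, donor_prev)
    if h is None:
        return NO_BOND
    n = donor.atoms["N"]
    c = acceptor.atoms["C"]
    o = acceptor.atoms["O"]
    r_on = float(np.linalg.norm(o - n))
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return NO_BOND
    return _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


# ---------------------------------------------------------------------------
# secondary-structure assignment

def _phi_psi(chain: Chain, i: int) -> Tuple[Optional[float], Optional[float]]:
    res = chain.residues[i]
    phi = psi = None
    if {"N", "CA", "C"} <= res.atoms.keys():
        if i > 0:
            prev = chain.residues[i - 1]
            if prev.kind == "aa" and "C" in prev.atoms:
                phi = dihedral(prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"])
        if i + 1 < len(chain.residues):
            nxt = chain.residues[i + 1]
            if nxt.kind == "aa" and "N" in nxt.atoms:
                psi = dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"])
    return phi, psi


def _collect_hbonds(model: StructuralModel, cutoff: float) -> set:
    """Set of (acceptor_key, donor_key): CO(acceptor) accepts H from NH(donor)."""
    entries = []  # (chain_index, pos_in_chain, residue)
    for ci, chain in enumerate(model.chains):
        for pi, res in enumerate(chain.residues):
            if res.kind == "aa":
                entries.append((ci, pi, res))
    ca_idx = [k for k, (_, _, r) in enumerate(entries) if "CA" in r.atoms]
    if not ca_idx:
        return set()
    ca = np.array([entries[k][2].atoms["CA"] for k in ca_idx])
    tree = cKDTree(ca)
    pairs = tree.query_pairs(9.0)  # CA-CA prune, as in classic DSSP
    bonds = set()

    def try_bond(di: int, ai: int) -> None:
        dci, dpi, donor = entries[di]
        aci, api, acceptor = entries[ai]
        if dci == aci and abs(dpi - api) < 2:
            return
        prev = None
        if dpi > 0 and model.chains[dci].residues[dpi - 1].kind == "aa":
            prev = model.chains[dci].residues[dpi - 1]
        e = hbond_energy(donor, acceptor, prev)
        if e < cutoff:
            bonds.add((acceptor.key, donor.key))

    for a, b in pairs:
        try_bond(ca_idx[a], ca_idx[b])
        try_bond(ca_idx[b], ca_idx[a])
    return bonds


def assign_secondary_structure(model: StructuralModel,
                               hbond_cutoff: float = HBOND_CUTOFF,
                               extend: bool = True) -> ResidueLabels:
    """Per-residue four-class labels from author records + H-bond detection.

    Helix: residues ``i..i+3`` covered by two consecutive i->i+4 hydrogen
    bonds (Kabsch–Sander 4-turns at ``i-1`` and ``i``). Sheet: membership in
    at least one inter-strand bridge; parallel and antiparallel bond patterns
    are treated identically and no ladder direction is recorded. Chains
    shorter than 3 residues are left unassigned.
    """
    labels = ResidueLabels()
    for res in model.residues():
        if res.kind == "nuc":
            labels.set(res, "nucleotide")

    hb = _collect_hbonds(model, hbond_cutoff)

    def bond(acc: Optional[Residue], don: Optional[Residue]) -> bool:
        if acc is None or don is None:
            return False
        return (acc.key, don.key) in hb

    detected: Dict[Tuple[str, int, str], str] = {}

    # helix: two consecutive 4-turns
    for chain in model.chains:
        rs = chain.residues
        if len(rs) < 3:
            continue

        def aa_at(i: int) -> Optional[Residue]:
            if 0 <= i < len(rs) and rs[i].kind == "aa":
                return rs[i]
            return None

        for i in range(1, len(rs) - 4):
            if bond(aa_at(i - 1), aa_at(i + 3)) and bond(aa_at(i), aa_at(i + 4)):
                for j in range(i, i + 4):
                    detected[rs[j].key] = "helix"

    # bridges: parallel or antiparallel Kabsch-Sander bond patterns
    entries = [(ci, pi, res) for ci, chain in enumerate(model.chains)
               for pi, res in enumerate(chain.residues) if res.kind == "aa"
               and "CA" in res.atoms]
    if entries:
        ca = np.array([e[2].atoms["CA"] for e in entries])
        tree = cKDTree(ca)
        for a, b in tree.query_pairs(6.5):  # bridge partners sit ~4.5-5.5 A apart
            ci_a, pi_a, res_a = entries[a]
            ci_b, pi_b, res_b = entries[b]
            if ci_a == ci_b and abs(pi_a - pi_b) < 3:
                continue

            def nb(ci: int, pi: int) -> Optional[Residue]:
                rs = model.chains[ci].residues
                if 0 <= pi < len(rs) and rs[pi].kind == "aa":
                    return rs[pi]
                return None

            i, j = nb(ci_a, pi_a), nb(ci_b, pi_b)
            im1, ip1 = nb(ci_a, pi_a - 1), nb(ci_a, pi_a + 1)
            jm1, jp1 = nb(ci_b, pi_b - 1), nb(ci_b, pi_b + 1)
            parallel = (bond(im1, j) and bond(j, ip1)) or (bond(jm1, i) and bond(i, jp1))
            antiparallel = (bond(i, j) and bond(j, i)) or (bond(im1, jp1) and bond(jm1, ip1))
            if parallel or antiparallel:
                # helix wins when a residue matches both patterns
                for key in (res_a.key, res_b.key):
                    if detected.get(key) != "helix":
                        detected[key] = "sheet"

    # short chains never receive detected labels
    short = {res.key for chain in model.chains if len(chain.residues) < 3
             for res in chain.residues}

    for key, cls in detected.items():
        if key in short:
            continue
        if labels.get_key(key) == "unassigned":
            labels._labels[key] = cls

    # author annotations override detected labels
    index: Dict[str, List[Residue]] = {}
    for chain in model.chains:
        index[chain.chain_id] = chain.residues
    for rec in model.author_ss:
        for res in index.get(rec.chain_id, []):
            if res.kind != "aa":
                continue
            if rec.start <= (res.seqid, res.icode) <= rec.end:
                labels._labels[res.key] = rec.ss_class

    if extend:
        labels = extend_by_ramachandran(labels, model)
    return labels


def _in_window(x: Optional[float], window: Tuple[float, float]) -> bool:
    return x is not None and window[0] < x < window[1]


def _psi_in_sheet(psi: Optional[float]) -> bool:
    if psi is None:
        return False
    lo_hi, wrap = SHEET_PSI_WINDOWS
    return (lo_hi[0] < psi <= lo_hi[1]) or (wrap[0] <= psi < wrap[1])


def extend_by_ramachandran(labels: ResidueLabels, model: StructuralModel) -> ResidueLabels:
    """Absorb unassigned neighbours of helices/sheets by torsion profile.

    Iterates to a fixed point; only converts unassigned -> helix/sheet, never
    the reverse. Residues lacking phi or psi (chain termini, breaks) are never
    extended.
    """
    out = labels.copy()
    for chain in model.chains:
        rs = chain.residues
        n = len(rs)
        if n < 2:
            continue
        phipsi = [(_phi_psi(chain, i) if rs[i].kind == "aa" else (None, None))
                  for i in range(n)]
        changed = True
        while changed:
            changed = False
            for i, res in enumerate(rs):
                if res.kind != "aa" or out.get(res) != "unassigned":
                    continue
                phi, psi = phipsi[i]
                if phi is None or psi is None:
                    continue
                neigh = {out.get(rs[j]) for j in (i - 1, i + 1) if 0 <= j < n}
                if "helix" in neigh and _in_window(phi, HELIX_PHI_WINDOW) \
                        and _in_window(psi, HELIX_PSI_WINDOW):
                    out._labels[res.key] = "helix"
                    changed = True
                elif "sheet" in neigh and _in_window(phi, SHEET_PHI_WINDOW) \
                        and _psi_in_sheet(psi):
                    out._labels[res.key] = "sheet"
                    changed = True
    return out
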