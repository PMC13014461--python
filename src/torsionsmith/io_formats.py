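"""AMBER-dialect file I/O.

Reads %FLAG/%FORMAT-sectioned prmtop topologies and writes the workflow's
output artifacts: frcmod parameter-modification files, parmed command
scripts, TRIPOS mol2 coordinate/charge files, and JSON ligand-fragment atom
maps.  A small prmtop writer exists so fixtures and fragments can round-trip
through the reader.

prmtop conventions honoured here:
  * charges are stored in internal units (elementary charge x 18.2223);
  * DIHEDRAL_FORCE_CONSTANT holds V_n/2, phases/equilibrium angles radians;
  * dihedral atom entries are 3*index, with a negative third atom marking a
    term whose 1-4 pair must not be counted (multi-term continuation or ring
    closure) and a negative fourth atom marking an improper;
  * Lennard-Jones parameters are the pairwise ACOEF/BCOEF tables.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ffcore import (AngleTerm, AtomRecord, BondTerm, Conformation,
                     FourierComponent, MoleculeTopology, Pair14, TorsionTerm)

log = logging.getLogger(__name__)

CHARGE_UNIT = 18.2223   # sqrt(kcal A/mol) per elementary charge, AMBER internal

_ELEMENTS = {1: "H", 6: "C", 7: "N", 8: "O", 16: "S", 9: "F", 15: "P",
             17: "Cl", 35: "Br", 53: "I"}
_Z = {v: k for k, v in _ELEMENTS.items()}


class TopologyFormatError(ValueError):
    """Malformed or incomplete prmtop content."""


# ---------------------------------------------------------------------------
# prmtop
# ---------------------------------------------------------------------------

_MANDATORY_FLAGS = (
    "POINTERS", "CHARGE", "MASS", "ATOM_TYPE_INDEX", "NONBONDED_PARM_INDEX",
    "BOND_FORCE_CONSTANT", "BOND_EQUIL_VALUE", "ANGLE_FORCE_CONSTANT",
    "ANGLE_EQUIL_VALUE", "DIHEDRAL_FORCE_CONSTANT", "DIHEDRAL_PERIODICITY",
    "DIHEDRAL_PHASE", "LENNARD_JONES_ACOEF", "LENNARD_JONES_BCOEF",
    "BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN", "ANGLES_INC_HYDROGEN",
    "ANGLES_WITHOUT_HYDROGEN", "DIHEDRALS_INC_HYDROGEN",
    "DIHEDRALS_WITHOUT_HYDROGEN", "EXCLUDED_ATOMS_LIST",
    "NUMBER_EXCLUDED_ATOMS", "AMBER_ATOM_TYPE",
)


def _parse_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    flag = None
    fmt = None
    for line in text.splitlines():
        if line.startswith("%VERSION") or line.startswith("%COMMENT"):
            continue
        if line.startswith("%FLAG"):
            flag = line.split()[1]
            sections[flag] = []
            fmt = None
        elif line.startswith("%FORMAT"):
            fmt = line
        elif flag is not None:
            sections[flag].append(line)
    return sections


def _floats(lines):
    return [float(t) for line in lines for t in line.split()]


def _ints(lines):
    return [int(t) for line in lines for t in line.split()]


def _a4(lines):
    out = []
    for line in lines:
        for k in range(0, len(line.rstrip("\n")), 4):
            tok = line[k:k + 4].strip()
            if tok:
                out.append(tok)
    return out


def read_topology(path) -> MoleculeTopology:
    """Parse a (gas-phase, single-residue) AMBER prmtop into a topology.

    Charges are converted to elementary charges, per-atom LJ parameters are
    recovered from the diagonal of the ACOEF/BCOEF tables, and the 1-4 pair
    list is rebuilt from the dihedral records, skipping continuation/ring
    (negative third atom) and improper (negative fourth atom) entries.
    """
    text = Path(path).read_text()
    sec = _parse_sections(text)
    for flagname in _MANDATORY_FLAGS:
        if flagname not in sec:
            raise TopologyFormatError(f"missing mandatory section %FLAG {flagname}")
    ptr = _ints(sec["POINTERS"])
    natom, ntypes = ptr[0], ptr[1]
    nbonh, mbona, ntheth, mtheta, nphih, mphia = ptr[2:8]
    charges = np.array(_floats(sec["CHARGE"])) / CHARGE_UNIT
    masses = _floats(sec["MASS"])
    if len(charges) != natom or len(masses) != natom:
        raise TopologyFormatError("pointer counts inconsistent with CHARGE/MASS")
    type_idx = _ints(sec["ATOM_TYPE_INDEX"])
    nb_idx = _ints(sec["NONBONDED_PARM_INDEX"])
    acoef = _floats(sec["LENNARD_JONES_ACOEF"])
    bcoef = _floats(sec["LENNARD_JONES_BCOEF"])
    atom_types = _a4(sec["AMBER_ATOM_TYPE"])
    if "ATOMIC_NUMBER" in sec:
        elements = [_ELEMENTS.get(z, "X") for z in _ints(sec["ATOMIC_NUMBER"])]
    else:
        elements = ["H" if m < 2.0 else "C" for m in masses]

    def lj_diag(t):
        k = nb_idx[ntypes * (t - 1) + (t - 1)] - 1
        a, b = acoef[k], bcoef[k]
        if a <= 0.0 or b <= 0.0:
            return 0.0, 0.0
        rmin = (2.0 * a / b) ** (1.0 / 6.0)
        eps = b * b / (4.0 * a)
        return rmin / 2.0, eps

    atoms = []
    for i in range(natom):
        rmh, eps = lj_diag(type_idx[i])
        atoms.append(AtomRecord(i, elements[i], atom_types[i],
                                float(charges[i]), float(masses[i]), rmh, eps))

    bk = _floats(sec["BOND_FORCE_CONSTANT"])
    bl = _floats(sec["BOND_EQUIL_VALUE"])
    bonds = []
    for arr in (_ints(sec["BONDS_INC_HYDROGEN"]), _ints(sec["BONDS_WITHOUT_HYDROGEN"])):
        for k in range(0, len(arr), 3):
            i, j, p = arr[k] // 3, arr[k + 1] // 3, arr[k + 2] - 1
            bonds.append(BondTerm(i, j, bk[p], bl[p]))
    if len(bonds) != nbonh + mbona:
        raise TopologyFormatError("pointer counts inconsistent with bond arrays")

    ak = _floats(sec["ANGLE_FORCE_CONSTANT"])
    at = _floats(sec["ANGLE_EQUIL_VALUE"])
    angles = []
    for arr in (_ints(sec["ANGLES_INC_HYDROGEN"]), _ints(sec["ANGLES_WITHOUT_HYDROGEN"])):
        for k in range(0, len(arr), 4):
            i, j, kk, p = arr[k] // 3, arr[k + 1] // 3, arr[k + 2] // 3, arr[k + 3] - 1
            angles.append(AngleTerm(i, j, kk, ak[p], float(np.rad2deg(at[p]))))
    if len(angles) != ntheth + mtheta:
        raise TopologyFormatError("pointer counts inconsistent with angle arrays")

    dk = _floats(sec["DIHEDRAL_FORCE_CONSTANT"])
    dn = _floats(sec["DIHEDRAL_PERIODICITY"])
    dph = _floats(sec["DIHEDRAL_PHASE"])
    nptra = len(dk)
    scee = _floats(sec["SCEE_SCALE_FACTOR"]) if "SCEE_SCALE_FACTOR" in sec else [1.2] * nptra
    scnb = _floats(sec["SCNB_SCALE_FACTOR"]) if "SCNB_SCALE_FACTOR" in sec else [2.0] * nptra

    # group multi-term dihedrals by (quad, improper) preserving order
    groups: dict = {}
    pairs14: list[Pair14] = []
    seen14 = set()
    ndihe = 0
    for arr in (_ints(sec["DIHEDRALS_INC_HYDROGEN"]), _ints(sec["DIHEDRALS_WITHOUT_HYDROGEN"])):
        for k in range(0, len(arr), 5):
            ndihe += 1
            i, j = arr[k] // 3, arr[k + 1] // 3
            k_raw, l_raw, p = arr[k + 2], arr[k + 3], arr[k + 4] - 1
            skip14 = k_raw < 0
            improper = l_raw < 0
            kk, l = abs(k_raw) // 3, abs(l_raw) // 3
            quad = (i, j, kk, l)
            comp = FourierComponent(2.0 * dk[p], int(round(dn[p])),
                                    float(np.rad2deg(dph[p])))
            key = (quad, improper)
            groups.setdefault(key, {"comps": [], "scee": scee[p], "scnb": scnb[p]})
            groups[key]["comps"].append(comp)
            if not skip14 and not improper:
                pk = (min(i, l), max(i, l))
                if pk not in seen14:
                    seen14.add(pk)
                    pairs14.append(Pair14(pk[0], pk[1], scee[p], scnb[p]))
    if ndihe != nphih + mphia:
        raise TopologyFormatError("pointer counts inconsistent with dihedral arrays")
    torsions = [TorsionTerm(quad, tuple(g["comps"]), g["scee"], g["scnb"], improper)
                for (quad, improper), g in groups.items()]

    nexc = _ints(sec["NUMBER_EXCLUDED_ATOMS"])
    exc_list = _ints(sec["EXCLUDED_ATOMS_LIST"])
    excluded = set()
    pos = 0
    for i in range(natom):
        for j in exc_list[pos:pos + nexc[i]]:
            if j > 0:
                excluded.add((min(i, j - 1), max(i, j - 1)))
        pos += nexc[i]
    excluded -= seen14
    return MoleculeTopology(atoms, bonds, angles, torsions, excluded, pairs14)


def _fmt_block(values, per_line, fmt):
    lines = []
    for k in range(0, len(values), per_line):
        lines.append("".join(fmt % v for v in values[k:k + per_line]))
    if not lines:
        lines = [""]
    return "\n".join(lines)


def write_topology(path, topology: MoleculeTopology, title: str = "torsionsmith") -> None:
    """Write the prmtop subset the reader understands (fixture/fragment use)."""
    atoms = topology.atoms
    natom = len(atoms)
    # LJ types keyed by (atom_type, rmin_half, epsilon)
    type_keys: list = []
    type_of = []
    for a in atoms:
        key = (a.atom_type, round(a.lj_rmin_half, 8), round(a.lj_epsilon, 8))
        if key not in type_keys:
            type_keys.append(key)
        type_of.append(type_keys.index(key) + 1)
    ntypes = len(type_keys)
    nb_idx = [0] * (ntypes * ntypes)
    acoef, bcoef = [], []
    cnt = 0
    for i in range(ntypes):
        for j in range(i + 1):
            rmin = type_keys[i][1] + type_keys[j][1]
            eps = float(np.sqrt(type_keys[i][2] * type_keys[j][2]))
            acoef.append(eps * rmin ** 12)
            bcoef.append(2.0 * eps * rmin ** 6)
            cnt += 1
            nb_idx[ntypes * i + j] = cnt
            nb_idx[ntypes * j + i] = cnt
    is_h = [a.element == "H" for a in atoms]

    bparams, bidx = [], {}
    brec_h, brec = [], []
    for b in topology.bonds:
        key = (b.k_b, b.l0)
        p = bidx.setdefault(key, len(bidx) + 1)
        if p > len(bparams):
            bparams.append(key)
        rec = [3 * b.i, 3 * b.j, p]
        (brec_h if is_h[b.i] or is_h[b.j] else brec).extend(rec)
    aparams, aidx = [], {}
    arec_h, arec = [], []
    for a in topology.angles:
        key = (a.k_a, float(np.deg2rad(a.theta0)))
        p = aidx.setdefault(key, len(aidx) + 1)
        if p > len(aparams):
            aparams.append(key)
        rec = [3 * a.i, 3 * a.j, 3 * a.k, p]
        (arec_h if any(is_h[x] for x in (a.i, a.j, a.k)) else arec).extend(rec)

    p14set = {(min(p.i, p.j), max(p.i, p.j)) for p in topology.pairs14}
    dparams, didx = [], {}
    drec_h, drec = [], []
    for t in topology.torsions:
        i, j, k, l = t.quad
        owns14 = (not t.is_improper) and (min(i, l), max(i, l)) in p14set
        for ci, c in enumerate(t.components):
            key = (c.v / 2.0, c.n, float(np.deg2rad(c.gamma)), t.scee, t.scnb)
            p = didx.setdefault(key, len(didx) + 1)
            if p > len(dparams):
                dparams.append(key)
            k_signed = 3 * k if (owns14 and ci == 0) else -3 * k
            l_signed = -3 * l if t.is_improper else 3 * l
            if k == 0 or l == 0:
                # sign carries meaning: keep atom 0 out of slots 3/4
                i, j, k, l = l, k, j, i
                k_signed = 3 * k if (owns14 and ci == 0) else -3 * k
                l_signed = -3 * l if t.is_improper else 3 * l
            rec = [3 * i, 3 * j, k_signed, l_signed, p]
            (drec_h if any(is_h[x] for x in t.quad) else drec).extend(rec)

    excl_by_atom = [[] for _ in range(natom)]
    allex = set(topology.excluded_pairs) | p14set
    for i, j in sorted(allex):
        excl_by_atom[i].append(j + 1)
    nexc, exc_list = [], []
    for i in range(natom):
        if excl_by_atom[i]:
            nexc.append(len(excl_by_atom[i]))
            exc_list.extend(sorted(excl_by_atom[i]))
        else:
            nexc.append(1)
            exc_list.append(0)

    nbonh, mbona = len(brec_h) // 3, len(brec) // 3
    ntheth, mtheta = len(arec_h) // 4, len(arec) // 4
    nphih, mphia = len(drec_h) // 5, len(drec) // 5
    ptr = [0] * 31
    ptr[0], ptr[1] = natom, ntypes
    ptr[2], ptr[3] = nbonh, mbona
    ptr[4], ptr[5] = ntheth, mtheta
    ptr[6], ptr[7] = nphih, mphia
    ptr[10] = len(exc_list)
    ptr[11] = 1  # NRES
    ptr[12], ptr[13], ptr[14] = mbona, mtheta, mphia
    ptr[15], ptr[16], ptr[17] = len(bparams), len(aparams), len(dparams)
    ptr[18] = ntypes

    def sect(flagname, fmtdecl, body):
        return f"%FLAG {flagname}\n%FORMAT{fmtdecl}\n{body}\n"

    e5 = "%24.16E"
    i8 = "%8d"
    names = [f"{a.element}{a.index + 1}" for a in atoms]
    out = ["%VERSION  VERSION_STAMP = V0001.000  DATE = torsionsmith\n"]
    out.append(sect("TITLE", "(20a4)", title[:80]))
    out.append(sect("POINTERS", "(10I8)", _fmt_block(ptr, 10, i8)))
    out.append(sect("ATOM_NAME", "(20a4)",
                    _fmt_block([f"{n:<4s}" for n in names], 20, "%s")))
    out.append(sect("CHARGE", "(3E24.16)",
                    _fmt_block([a.charge * CHARGE_UNIT for a in atoms], 3, e5)))
    out.append(sect("ATOMIC_NUMBER", "(10I8)",
                    _fmt_block([_Z.get(a.element, 0) for a in atoms], 10, i8)))
    out.append(sect("MASS", "(3E24.16)", _fmt_block([a.mass for a in atoms], 3, e5)))
    out.append(sect("ATOM_TYPE_INDEX", "(10I8)", _fmt_block(type_of, 10, i8)))
    out.append(sect("NUMBER_EXCLUDED_ATOMS", "(10I8)", _fmt_block(nexc, 10, i8)))
    out.append(sect("NONBONDED_PARM_INDEX", "(10I8)", _fmt_block(nb_idx, 10, i8)))
    out.append(sect("RESIDUE_LABEL", "(20a4)", "MOL "))
    out.append(sect("RESIDUE_POINTER", "(10I8)", _fmt_block([1], 10, i8)))
    out.append(sect("BOND_FORCE_CONSTANT", "(3E24.16)",
                    _fmt_block([p[0] for p in bparams], 5, e5)))
    out.append(sect("BOND_EQUIL_VALUE", "(3E24.16)",
                    _fmt_block([p[1] for p in bparams], 5, e5)))
    out.append(sect("ANGLE_FORCE_CONSTANT", "(3E24.16)",
                    _fmt_block([p[0] for p in aparams], 5, e5)))
    out.append(sect("ANGLE_EQUIL_VALUE", "(3E24.16)",
                    _fmt_block([p[1] for p in aparams], 5, e5)))
    out.append(sect("DIHEDRAL_FORCE_CONSTANT", "(3E24.16)",
                    _fmt_block([p[0] for p in dparams], 5, e5)))
    out.append(sect("DIHEDRAL_PERIODICITY", "(3E24.16)",
                    _fmt_block([float(p[1]) for p in dparams], 5, e5)))
    out.append(sect("DIHEDRAL_PHASE", "(3E24.16)",
                    _fmt_block([p[2] for p in dparams], 5, e5)))
    out.append(sect("SCEE_SCALE_FACTOR", "(3E24.16)",
                    _fmt_block([p[3] for p in dparams], 5, e5)))
    out.append(sect("SCNB_SCALE_FACTOR", "(3E24.16)",
                    _fmt_block([p[4] for p in dparams], 5, e5)))
    out.append(sect("LENNARD_JONES_ACOEF", "(3E24.16)", _fmt_block(acoef, 3, e5)))
    out.append(sect("LENNARD_JONES_BCOEF", "(3E24.16)", _fmt_block(bcoef, 3, e5)))
    out.append(sect("BONDS_INC_HYDROGEN", "(10I8)", _fmt_block(brec_h, 10, i8)))
    out.append(sect("BONDS_WITHOUT_HYDROGEN", "(10I8)", _fmt_block(brec, 10, i8)))
    out.append(sect("ANGLES_INC_HYDROGEN", "(10I8)", _fmt_block(arec_h, 10, i8)))
    out.append(sect("ANGLES_WITHOUT_HYDROGEN", "(10I8)", _fmt_block(arec, 10, i8)))
    out.append(sect("DIHEDRALS_INC_HYDROGEN", "(10I8)", _fmt_block(drec_h, 10, i8)))
    out.append(sect("DIHEDRALS_WITHOUT_HYDROGEN", "(10I8)", _fmt_block(drec, 10, i8)))
    out.append(sect("EXCLUDED_ATOMS_LIST", "(10I8)", _fmt_block(exc_list, 10, i8)))
    out.append(sect("AMBER_ATOM_TYPE", "(20a4)",
                    _fmt_block([f"{a.atom_type:<4s}" for a in atoms], 20, "%s")))
    Path(path).write_text("".join(out))


# ---------------------------------------------------------------------------
# frcmod
# ---------------------------------------------------------------------------

@dataclass
class FrcmodDocument:
    """Parsed/buildable frcmod with DIHE records keyed by atom-type quadruple."""
    title: str = "torsionsmith torsion refit"
    dihe: dict[tuple[str, str, str, str], TorsionTerm] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [self.title, "", "MASS", "", "BOND", "", "ANGLE", "", "DIHE"]
        for types, term in self.dihe.items():
            label = "-".join(f"{t:<2s}" for t in types)
            comps = term.components
            for ci, c in enumerate(comps):
                # AMBER continuation: negative periodicity on non-final lines
                per = -c.n if ci < len(comps) - 1 else c.n
                lines.append(f"{label} {1:4d} {c.v / 2.0:10.5f} {c.gamma:8.2f} "
                             f"{float(per):8.1f}    SCEE={term.scee:.3f} "
                             f"SCNB={term.scnb:.3f}")
        lines += ["", "IMPROPER", "", "NONBON", ""]
        return "\n".join(lines)


def type_quadruple(topology: MoleculeTopology, quad) -> tuple[str, str, str, str]:
    """Canonical atom-type quadruple: the lexicographically smaller of the two
    reading directions."""
    tq = tuple(topology.atoms[a].atom_type for a in quad)
    return min(tq, tq[::-1])


def write_frcmod(fit_terms: dict, topology: MoleculeTopology,
                 prune_floor: float = 0.005,
                 title: str = "torsionsmith torsion refit") -> FrcmodDocument:
    """Build a FrcmodDocument from fitted torsion terms keyed by atom quad.

    Components with V_n below ``prune_floor`` are dropped (logged); a term
    losing every component is emitted with a single zero line so the type is
    still overridden.
    """
    doc = FrcmodDocument(title=title)
    for quad, term in fit_terms.items():
        kept = tuple(c for c in term.components if abs(c.v) >= prune_floor)
        dropped = len(term.components) - len(kept)
        if dropped:
            log.info("frcmod: dropped %d sub-floor component(s) of %s", dropped, quad)
        if not kept:
            kept = (FourierComponent(0.0, 1, 0.0),)
        doc.dihe[type_quadruple(topology, quad)] = TorsionTerm(
            tuple(quad), kept, term.scee, term.scnb)
    return doc


_DIHE_RE = re.compile(
    r"^\s*(\S{1,2})\s*-\s*(\S{1,2})\s*-\s*(\S{1,2})\s*-\s*(\S{1,2})\s+(\d+)\s+"
    r"([-\d.Ee+]+)\s+([-\d.Ee+]+)\s+([-\d.Ee+]+)(.*)$")


def read_frcmod(path) -> FrcmodDocument:
    doc = FrcmodDocument()
    lines = Path(path).read_text().splitlines()
    doc.title = lines[0] if lines else ""
    section = None
    pending: list = []
    pending_types = None
    pending_sc = (1.2, 2.0)

    def flush():
        nonlocal pending, pending_types
        if pending_types is not None and pending:
            doc.dihe[pending_types] = TorsionTerm((0, 1, 2, 3), tuple(pending),
                                                  *pending_sc)
        pending, pending_types = [], None

    for line in lines[1:]:
        token = line.strip().upper()
        if token in ("MASS", "BOND", "ANGLE", "DIHE", "IMPROPER", "NONBON"):
            flush()
            section = token
            continue
        if section != "DIHE" or not line.strip():
            continue
        m = _DIHE_RE.match(line)
        if not m:
            continue
        types = tuple(m.group(g) for g in range(1, 5))
        divider = int(m.group(5))
        pk, phase, per = (float(m.group(g)) for g in (6, 7, 8))
        tail = m.group(9)
        scee = float(re.search(r"SCEE\s*=\s*([\d.]+)", tail).group(1)) \
            if "SCEE" in tail else 1.2
        scnb = float(re.search(r"SCNB\s*=\s*([\d.]+)", tail).group(1)) \
            if "SCNB" in tail else 2.0
        if pending_types is not None and types != pending_types:
            flush()
        pending_types = types
        pending_sc = (scee, scnb)
        pending.append(FourierComponent(2.0 * pk / divider, int(round(abs(per))),
                                        phase))
        if per > 0:
            flush()
    flush()
    return doc


def apply_frcmod(topology: MoleculeTopology, doc: FrcmodDocument) -> MoleculeTopology:
    """Override every proper torsion whose type quadruple has a DIHE record."""
    out = topology
    for t in topology.torsions:
        if t.is_improper:
            continue
        tq = type_quadruple(topology, t.quad)
        if tq in doc.dihe:
            new = doc.dihe[tq]
            out = out.replace_torsion(
                t.quad, TorsionTerm(t.quad, new.components, new.scee, new.scnb))
    return out


# ---------------------------------------------------------------------------
# parmed script
# ---------------------------------------------------------------------------

@dataclass
class ParmedScript:
    commands: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        return "\n".join(["setOverwrite True"] + self.commands +
                         ["outparm updated.prmtop", ""])


@dataclass
class FitEntry:
    """One fitted torsion destined for output: the quad it was fitted on, the
    fitted term, the topology it indexes into, and (for fragment fits) the
    atom map back to the parent ligand."""
    quad: tuple[int, int, int, int]
    term: TorsionTerm
    topology: MoleculeTopology
    atom_map: "AtomMap | None" = None


def write_parmed_script(entries, parent_topology: MoleculeTopology,
                        merge_policy: str = "last_wins") -> ParmedScript:
    """Consolidate per-torsion (possibly per-fragment) fits into one parmed
    command script addressing the parent ligand's atom types.

    Duplicate updates to a type quadruple are deduplicated when identical;
    genuine conflicts are resolved by ``merge_policy`` ("last_wins" or
    "first_wins") and recorded on the script.
    """
    if merge_policy not in ("last_wins", "first_wins"):
        raise ValueError(f"unknown merge policy {merge_policy!r}")
    merged: dict[tuple, TorsionTerm] = {}
    conflicts = []
    for e in entries:
        if e.atom_map is not None:
            parent_quad = tuple(e.atom_map.to_parent(a) for a in e.quad)
            tq = type_quadruple(parent_topology, parent_quad)
        else:
            tq = type_quadruple(parent_topology, e.quad)
        if tq in merged and merged[tq] != e.term:
            conflicts.append(f"conflicting update for {tq}; {merge_policy}")
            log.warning("parmed merge conflict on %s (%s)", tq, merge_policy)
            if merge_policy == "first_wins":
                continue
        merged[tq] = e.term

    script = ParmedScript(conflicts=conflicts)
    for tq, term in merged.items():
        masks = " ".join(f"@%{t}" for t in tq)
        script.commands.append(f"deleteDihedral {masks}")
        for c in term.components:
            script.commands.append(
                f"addDihedral {masks} {c.v / 2.0:.6f} {c.n} {c.gamma:.2f} "
                f"{term.scee:.3f} {term.scnb:.3f}")
    return script


# ---------------------------------------------------------------------------
# mol2
# ---------------------------------------------------------------------------

def write_mol2(path, topology: MoleculeTopology, conformation: Conformation,
               charges=None, name: str = "MOL") -> None:
    """TRIPOS mol2 with 1-based atom ids and charges in the charge column."""
    q = np.array([a.charge for a in topology.atoms]) if charges is None \
        else np.asarray(charges, float)
    if len(q) != topology.n_atoms:
        raise ValueError("charge vector length mismatch")
    xyz = conformation.coordinates
    lines = ["@<TRIPOS>MOLECULE", name,
             f"{topology.n_atoms:d} {len(topology.bonds):d} 1 0 0",
             "SMALL", "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for a in topology.atoms:
        lines.append(f"{a.index + 1:>7d} {a.element}{a.index + 1:<4d} "
                     f"{xyz[a.index, 0]:>10.4f} {xyz[a.index, 1]:>10.4f} "
                     f"{xyz[a.index, 2]:>10.4f} {a.atom_type:<6s} 1 {name:<4s} "
                     f"{q[a.index]:>10.6f}")
    lines.append("@<TRIPOS>BOND")
    for n, b in enumerate(topology.bonds, start=1):
        order = "ar" if b.order == 2 else str(b.order)
        lines.append(f"{n:>6d} {b.i + 1:>5d} {b.j + 1:>5d} {order}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mol2(path):
    """Return (elements, coordinates, charges, bonds) from a TRIPOS mol2."""
    elements, coords, charges, bonds = [], [], [], []
    section = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("@<TRIPOS>"):
            section = line.strip()
            continue
        if not line.strip():
            continue
        if section == "@<TRIPOS>ATOM":
            t = line.split()
            elements.append(re.sub(r"\d+$", "", t[1]))
            coords.append([float(x) for x in t[2:5]])
            charges.append(float(t[8]) if len(t) > 8 else 0.0)
        elif section == "@<TRIPOS>BOND":
            t = line.split()
            order = 2 if t[3] in ("ar", "2") else 1
            bonds.append((int(t[1]) - 1, int(t[2]) - 1, order))
    return elements, np.array(coords), np.array(charges), bonds


# ---------------------------------------------------------------------------
# atom maps
# ---------------------------------------------------------------------------

@dataclass
class AtomMap:
    """Bijective fragment-to-parent index map; cap atoms have no parent."""
    fragment_id: str
    pairs: list[tuple[int, int]]     # (fragment index, parent index)
    caps: list[int]                  # fragment atoms with no parent

    def __post_init__(self):
        fr = [f for f, _ in self.pairs]
        pa = [p for _, p in self.pairs]
        if len(set(fr)) != len(fr) or len(set(pa)) != len(pa):
            raise ValueError("atom map must be injective")
        if set(fr) & set(self.caps):
            raise ValueError("cap atoms cannot be mapped")
        self._to_parent = dict(self.pairs)
        self._to_fragment = {p: f for f, p in self.pairs}

    def to_parent(self, fragment_index: int) -> int:
        if fragment_index in self._to_parent:
            return self._to_parent[fragment_index]
        raise KeyError(f"fragment atom {fragment_index} of {self.fragment_id} "
                       f"is a cap or unmapped")

    def to_fragment(self, parent_index: int) -> int:
        return self._to_fragment[parent_index]

    def to_json(self) -> str:
        return json.dumps({"fragment_id": self.fragment_id,
                           "pairs": [list(p) for p in self.pairs],
                           "caps": list(self.caps)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AtomMap":
        d = json.loads(text)
        return cls(d["fragment_id"], [tuple(p) for p in d["pairs"]], d["caps"])


def write_atom_map(path, amap: AtomMap) -> None:
    Path(path).write_text(amap.to_json())


def read_atom_map(path) -> AtomMap:
    return AtomMap.from_json(Path(path).read_text())
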