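"""File formats: hkl, phs, hlc, PDB, FASTA, site lists, fractional models.

Text formats are whitespace-tolerant on read and fixed-width deterministic
on write, so identical runs produce byte-identical output.  Dialects:

hkl   : ``h k l F sigF`` one reflection per line
phs   : ``h k l F fom phi`` (phi degrees; fom clipped to [0,1] with warning)
hlc   : ``h k l A B C D`` Hendrickson-Lattman coefficients
sites : ``element x y z occ`` fractional coordinates
frac  : crystal-coordinate model — ``CELL a b c alpha beta gamma``,
        optional ``SPAG symbol``, then ``element x y z occ B`` per atom,
        fractional coordinates
PDB   : via gemmi (ATOM/HETATM + CRYST1)
FASTA : via Biopython
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AtomicModel
from .reflections import ReflectionSet
from .symmetry import SpaceGroup, UnitCell

__all__ = [
    "read_hkl", "write_hkl", "read_phs", "write_phs", "read_hlc", "write_hlc",
    "read_sites", "write_sites", "read_pdb", "write_pdb",
    "read_fasta", "write_fasta", "read_frac_model", "write_frac_model",
]


class FileFormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _parse_rows(path, n_min, n_max, kind):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if not n_min <= len(parts) <= n_max:
                raise FileFormatError(
                    f"{path}:{ln}: expected {n_min}-{n_max} fields for {kind}, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(([int(parts[i]) for i in range(3)],
                             [float(x) for x in parts[3:]], ln))
            except ValueError as exc:
                raise FileFormatError(f"{path}:{ln}: non-numeric field ({exc})") from None
    if not rows:
        raise FileFormatError(f"{path}: no reflections found")
    return rows


def _check_unique(hkl, path):
    if len(np.unique(hkl, axis=0)) != len(hkl):
        seen = set()
        for i, h in enumerate(map(tuple, hkl)):
            if h in seen:
                raise FileFormatError(f"{path}: duplicate index {h} (row {i + 1})")
            seen.add(h)


def read_hkl(path, cell: UnitCell | None = None, sg: SpaceGroup | None = None) -> ReflectionSet:
    rows = _parse_rows(path, 5, 5, "hkl (h k l F sigF)")
    hkl = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    _check_unique(hkl, path)
    return ReflectionSet(hkl, F=vals[:, 0], sigF=vals[:, 1], cell=cell, spacegroup=sg)


def write_hkl(refl: ReflectionSet, path) -> None:
    with open(path, "w") as fh:
        for h, f, s in zip(refl.hkl, refl.F, refl.sigF):
            fh.write(f"{h[0]:4d} {h[1]:4d} {h[2]:4d} {f:14.6f} {s:14.6f}\n")


def read_phs(path, cell=None, sg=None) -> ReflectionSet:
    rows = _parse_rows(path, 6, 6, "phs (h k l F fom phi)")
    hkl = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    _check_unique(hkl, path)
    fom = vals[:, 1]
    if np.any((fom < 0) | (fom > 1)):
        warnings.warn(f"{path}: figures of merit outside [0, 1] clipped", stacklevel=2)
        fom = np.clip(fom, 0.0, 1.0)
    return ReflectionSet(
        hkl, F=vals[:, 0], fom=fom, phi=vals[:, 2] % 360.0, cell=cell, spacegroup=sg
    )


def write_phs(refl: ReflectionSet, path) -> None:
    phi = np.where(np.isnan(refl.phi), 0.0, refl.phi % 360.0)
    fom = np.where(np.isnan(refl.fom), 0.0, refl.fom)
    with open(path, "w") as fh:
        for h, f, m, p in zip(refl.hkl, refl.F, fom, phi):
            fh.write(f"{h[0]:4d} {h[1]:4d} {h[2]:4d} {f:14.6f} {m:8.4f} {p:10.4f}\n")


def read_hlc(path, cell=None, sg=None) -> ReflectionSet:
    """HL-coefficient records; phase and fom are the distribution centroid.

    Rows with all-zero coefficients yield fom 0 and a stable phase of 0.
    """
    from .densitymod import _hl_centroid

    rows = _parse_rows(path, 7, 7, "hlc (h k l A B C D)")
    hkl = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    _check_unique(hkl, path)
    hl = vals[:, :4]
    phi, fom = _hl_centroid(hl)
    flat = np.all(hl == 0.0, axis=1)
    phi[flat] = 0.0
    fom[flat] = 0.0
    return ReflectionSet(
        hkl, F=np.ones(len(hkl)), phi=phi, fom=np.clip(fom, 0, 1), hl=hl,
        cell=cell, spacegroup=sg,
    )


def write_hlc(refl: ReflectionSet, path) -> None:
    if refl.hl is None:
        raise ValueError("reflection set carries no HL coefficients")
    with open(path, "w") as fh:
        for h, (a, b, c, d) in zip(refl.hkl, refl.hl):
            fh.write(
                f"{h[0]:4d} {h[1]:4d} {h[2]:4d} "
                f"{a:12.5f} {b:12.5f} {c:12.5f} {d:12.5f}\n"
            )


def read_sites(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Substructure sites: (elements, fractional positions, occupancies)."""
    elements, pos, occ = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 5:
                raise FileFormatError(
                    f"{path}:{ln}: expected 'element x y z occ', got {len(parts)} fields"
                )
            try:
                elements.append(parts[0])
                pos.append([float(x) for x in parts[1:4]])
                occ.append(float(parts[4]))
            except ValueError as exc:
                raise FileFormatError(f"{path}:{ln}: non-numeric field ({exc})") from None
    return (np.array(elements, dtype=object),
            np.array(pos) % 1.0, np.array(occ))


def write_sites(elements, frac_positions, occupancies, path) -> None:
    with open(path, "w") as fh:
        for el, p, o in zip(elements, np.asarray(frac_positions) % 1.0, occupancies):
            fh.write(f"{el:2s} {p[0]:10.6f} {p[1]:10.6f} {p[2]:10.6f} {o:8.4f}\n")


# -- PDB via gemmi ----------------------------------------------------------

_GEMMI_ELEMENT = {"HV": "Hg"}


def write_pdb(model: AtomicModel, cell: UnitCell, path, sg: SpaceGroup | None = None) -> None:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    st.spacegroup_hm = sg.hm_symbol if sg is not None else "P 1"
    mdl = gemmi.Model("1")
    xyz = model.xyz_orth(cell)
    # gemmi's add_* methods copy, so residues and chains must be complete
    # before they are attached
    order: list[tuple[str, int]] = []
    grouped: dict[tuple[str, int], list[int]] = {}
    for i in range(len(model)):
        key = (str(model.chain[i]), int(model.resseq[i]))
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(i)
    chain_order: list[str] = []
    by_chain: dict[str, list[tuple[int, gemmi.Residue]]] = {}
    for cid, seq in order:
        res = gemmi.Residue()
        res.name = str(model.resname[grouped[(cid, seq)][0]])
        res.seqid = gemmi.SeqId(seq, " ")
        for i in grouped[(cid, seq)]:
            at = gemmi.Atom()
            at.name = str(model.name[i])
            at.element = gemmi.Element(
                _GEMMI_ELEMENT.get(model.elements[i], model.elements[i])
            )
            at.pos = gemmi.Position(*xyz[i])
            at.occ = float(model.occ[i])
            at.b_iso = float(model.b[i])
            res.add_atom(at)
        if cid not in by_chain:
            by_chain[cid] = []
            chain_order.append(cid)
        by_chain[cid].append((seq, res))
    for cid in chain_order:
        ch = gemmi.Chain(cid)
        for _, res in by_chain[cid]:
            ch.add_residue(res)
        mdl.add_chain(ch)
    st.add_model(mdl)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def read_pdb(path) -> tuple[AtomicModel, UnitCell, str]:
    st = gemmi.read_pdb(str(path))
    c = st.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    elements, xyz, occ, b, name, resname, resseq, chain = ([] for _ in range(8))
    for mdl in st:
        for ch in mdl:
            for res in ch:
                for at in res:
                    el = at.element.name.upper()
                    elements.append("HV" if el == "HG" else el)
                    xyz.append([at.pos.x, at.pos.y, at.pos.z])
                    occ.append(at.occ)
                    b.append(max(at.b_iso, 1e-3))
                    name.append(at.name)
                    resname.append(res.name)
                    resseq.append(res.seqid.num)
                    chain.append(ch.name)
        break  # first model only
    model = AtomicModel.from_orthogonal(
        np.array(elements, dtype=object), np.array(xyz), cell,
        occ=np.array(occ), b=np.array(b),
        name=np.array(name, dtype=object), resname=np.array(resname, dtype=object),
        resseq=np.array(resseq), chain=np.array(chain, dtype=object),
    )
    return model, cell, (st.spacegroup_hm or "P 1").replace(" ", "")


# -- FASTA via Biopython ----------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path), "fasta",
    )


# -- fractional-coordinate ("crystal coordinates") model --------------------

def read_frac_model(path) -> tuple[AtomicModel, UnitCell, str | None]:
    cell = None
    sg_symbol = None
    elements, pos, occ, b = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            key = parts[0].upper()
            try:
                if key == "CELL":
                    cell = UnitCell(*[float(x) for x in parts[1:7]])
                elif key in ("SPAG", "LATT"):
                    sg_symbol = parts[1] if len(parts) > 1 else None
                else:
                    if len(parts) != 6:
                        raise FileFormatError(
                            f"{path}:{ln}: expected 'element x y z occ B'"
                        )
                    elements.append(parts[0])
                    pos.append([float(x) for x in parts[1:4]])
                    occ.append(float(parts[4]))
                    b.append(float(parts[5]))
            except FileFormatError:
                raise
            except (ValueError, TypeError) as exc:
                raise FileFormatError(f"{path}:{ln}: {exc}") from None
    if cell is None:
        raise FileFormatError(f"{path}: missing CELL record")
    if not elements:
        raise FileFormatError(f"{path}: no atom records")
    model = AtomicModel(np.array(elements, dtype=object), np.array(pos),
                        occ=np.array(occ), b=np.array(b))
    return model, cell, sg_symbol


def write_frac_model(model: AtomicModel, cell: UnitCell, path, sg: SpaceGroup | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"CELL {cell.a:10.5f} {cell.b:10.5f} {cell.c:10.5f} "
            f"{cell.alpha:8.3f} {cell.beta:8.3f} {cell.gamma:8.3f}\n"
        )
        if sg is not None:
            fh.write(f"SPAG {sg.symbol}\n")
        for el, p, o, bb in zip(model.elements, model.xyz_frac, model.occ, model.b):
            fh.write(
                f"{el:2s} {p[0]:10.6f} {p[1]:10.6f} {p[2]:10.6f} {o:8.4f} {bb:8.3f}\n"
            )
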