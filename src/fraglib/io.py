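"""Reading and writing fragment libraries and native backbone structures.

Two text formats are supported:

**NNMake dialect** (read/write).  The classic fragment-file layout: one block
per target position introduced by a header line ``position: P neighbors: N``,
followed by N fragment blocks separated by blank lines.  Each residue line
carries ``source_id chain source_resnum aa ss phi psi omega``.  A fragment's
predicted RMSD, when known, is stored on a ``#predRMSD <value>`` comment line
immediately preceding its block; plain NNMake text has no such field and
readers that do not know the convention skip the comment.  Missing angles are
serialized as the sentinel ``9999.000``, which cannot collide with a real
angle in (-180, 180].

**Extended format** (read/write).  A structured-text companion format carrying
per-residue backbone coordinates (N/CA/C/O/CB) in addition to angles, which
the pairwise-distance metrics and 2D potentials require and NNMake text
cannot express.  See :func:`write_extended_library` for the exact schema.

Native structures are read from PDB files (ATOM records of one chain) via
Biopython.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .core import Fragment, FragmentLibrary, FragmentResidue, TargetStructure
from .geometry import MISSING_ANGLE_SENTINEL, normalize_angle

logger = logging.getLogger(__name__)

__all__ = [
    "read_nnmake_library",
    "write_nnmake_library",
    "read_extended_library",
    "write_extended_library",
    "read_backbone_pdb",
]


class FragmentParseError(ValueError):
    """Malformed fragment-library text; message carries the offending line."""


def _angle_out(value: float) -> str:
    if value is None or np.isnan(value):
        return f"{MISSING_ANGLE_SENTINEL:9.3f}"
    return f"{value:9.3f}"


def _angle_in(token: str, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError as exc:
        raise FragmentParseError(f"line {lineno}: bad angle token {token!r}") from exc
    if v == MISSING_ANGLE_SENTINEL:
        return float("nan")
    if not -360.0 <= v <= 360.0:
        raise FragmentParseError(f"line {lineno}: angle {v} outside valid range")
    return normalize_angle(v)


# ---------------------------------------------------------------------------
# NNMake dialect
# ---------------------------------------------------------------------------

def write_nnmake_library(lib: FragmentLibrary, path) -> Path:
    """Serialize a library to NNMake-style text (angles to 3 decimals)."""
    lib.validate()
    if lib.n_fragments() == 0:
        raise ValueError("refusing to serialize an empty library")
    lines: list[str] = []
    for pos in sorted(lib.positions):
        frags = lib.positions[pos]
        if not frags:
            continue
        lines.append(f" position: {pos:12d} neighbors: {len(frags):10d}")
        lines.append("")
        for frag in frags:
            if frag.pred_rmsd is not None:
                lines.append(f"#predRMSD {frag.pred_rmsd:.3f}")
            src = (frag.source_id or "xxxx_A").split("_")
            pdb_id = src[0]
            chain = src[1] if len(src) > 1 else "A"
            for j, r in enumerate(frag.residues):
                lines.append(
                    f" {pdb_id:>4s} {chain:1s} {j + 1:5d} {r.aa:1s} {r.ss:1s}"
                    f" {_angle_out(r.phi)} {_angle_out(r.psi)} {_angle_out(r.omega)}"
                )
            lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_nnmake_library(path, target_length: int | None = None) -> FragmentLibrary:
    """Parse an NNMake-dialect fragment file.

    ``target_length`` defaults to the largest residue index any fragment
    covers.  The declared neighbor count of every position header is checked
    against the number of fragment blocks actually present.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FragmentParseError(f"{path}: empty fragment file")

    positions: dict[int, list[Fragment]] = {}
    cur_pos: int | None = None
    declared: dict[int, int] = {}
    pending_rmsd: float | None = None
    block: list[tuple[int, list[str]]] = []

    def flush_block():
        nonlocal block, pending_rmsd
        if not block:
            return
        if cur_pos is None:
            raise FragmentParseError(
                f"line {block[0][0]}: residue line before any position header")
        residues = []
        source = None
        for lineno, tok in block:
            if len(tok) != 8:
                raise FragmentParseError(
                    f"line {lineno}: expected 8 columns "
                    f"(source chain resnum aa ss phi psi omega), got {len(tok)}")
            source = f"{tok[0]}_{tok[1]}"
            residues.append(FragmentResidue(
                aa=tok[3], ss=tok[4],
                phi=_angle_in(tok[5], lineno), psi=_angle_in(tok[6], lineno),
                omega=_angle_in(tok[7], lineno)))
        positions.setdefault(cur_pos, []).append(
            Fragment(start_pos=cur_pos, residues=residues,
                     pred_rmsd=pending_rmsd, source_id=source))
        block = []
        pending_rmsd = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            flush_block()
            continue
        tok = line.split()
        if tok[0] == "position:":
            flush_block()
            if len(tok) < 4 or tok[2] != "neighbors:":
                raise FragmentParseError(f"line {lineno}: malformed position header {line!r}")
            try:
                cur_pos = int(tok[1])
                declared[cur_pos] = int(tok[3])
            except ValueError as exc:
                raise FragmentParseError(f"line {lineno}: malformed position header") from exc
            continue
        if tok[0] == "#predRMSD":
            flush_block()
            try:
                pending_rmsd = float(tok[1])
            except (IndexError, ValueError) as exc:
                raise FragmentParseError(f"line {lineno}: malformed #predRMSD line") from exc
            if pending_rmsd < 0:
                raise FragmentParseError(f"line {lineno}: negative predRMSD")
            continue
        if line.lstrip().startswith("#"):
            continue
        block.append((lineno, tok))
    flush_block()

    for pos, n in declared.items():
        actual = len(positions.get(pos, []))
        if actual != n:
            raise FragmentParseError(
                f"position {pos}: header declares {n} neighbors but {actual} "
                f"fragment blocks found")

    if not positions:
        raise FragmentParseError(f"{path}: no fragments parsed")
    if target_length is None:
        target_length = max(f.end_pos for frs in positions.values() for f in frs)
    return FragmentLibrary(target_length=target_length, positions=positions)


# ---------------------------------------------------------------------------
# Extended coordinate-bearing format
# ---------------------------------------------------------------------------

_EXT_MAGIC = "# fraglib-extended 1"
_EXT_ATOMS = ("N", "CA", "C", "O", "CB")


def write_extended_library(lib: FragmentLibrary, path) -> Path:
    """Serialize a coordinate-bearing library.

    Schema (one record per fragment)::

        # fraglib-extended 1
        target_length <L>
        fragment start <p> length <n> pred_rmsd <r|-> source <id|->
        R <aa> <ss> <phi> <psi> <omega> <theta> <tau> <N xyz> <CA xyz> <C xyz> <O xyz> <CB xyz>
        ... (n residue lines) ...
        end

    Angles use the 9999.000 missing sentinel; all five atoms are written (O
    and CB may be NaN if genuinely absent).
    """
    lib.validate()
    if lib.n_fragments() == 0:
        raise ValueError("refusing to serialize an empty library")
    lines = [_EXT_MAGIC, f"target_length {lib.target_length}"]
    for pos in sorted(lib.positions):
        for frag in lib.positions[pos]:
            if not frag.has_coords:
                raise ValueError(
                    f"extended format requires coordinates; fragment at position "
                    f"{pos} has none")
            pr = "-" if frag.pred_rmsd is None else f"{frag.pred_rmsd:.4f}"
            src = frag.source_id or "-"
            lines.append(f"fragment start {pos} length {len(frag)} "
                         f"pred_rmsd {pr} source {src}")
            for r in frag.residues:
                parts = [
                    "R", r.aa, r.ss,
                    _angle_out(r.phi).strip(), _angle_out(r.psi).strip(),
                    _angle_out(r.omega).strip(), _angle_out(r.theta).strip(),
                    _angle_out(r.tau).strip(),
                ]
                for atom in _EXT_ATOMS:
                    xyz = r.coords.get(atom)
                    if xyz is None:
                        parts.extend(["nan"] * 3)
                    else:
                        parts.extend(f"{v:.4f}" for v in xyz)
                lines.append(" ".join(parts))
            lines.append("end")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_extended_library(path, recompute_angles: bool = False) -> FragmentLibrary:
    """Parse the extended format.

    With ``recompute_angles=True`` the stored angles are ignored and all five
    angle kinds are recomputed from the fragment's own coordinates (boundary
    values then come out missing, since the source-protein context is gone).
    """
    from .geometry import backbone_angles_from_coords

    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != _EXT_MAGIC:
        raise FragmentParseError(f"{path}: not a fraglib-extended file")

    target_length: int | None = None
    positions: dict[int, list[Fragment]] = {}
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if tok[0] == "target_length":
            target_length = int(tok[1])
            continue
        if tok[0] != "fragment":
            raise FragmentParseError(f"line {i}: expected 'fragment' record, got {line!r}")
        kv = dict(zip(tok[1::2], tok[2::2]))
        start = int(kv["start"])
        length = int(kv["length"])
        pred_rmsd = None if kv.get("pred_rmsd", "-") == "-" else float(kv["pred_rmsd"])
        if pred_rmsd is not None and pred_rmsd < 0:
            raise FragmentParseError(f"line {i}: pred_rmsd {pred_rmsd} is negative")
        source = None if kv.get("source", "-") == "-" else kv["source"]
        residues = []
        for j in range(length):
            if i >= len(lines):
                raise FragmentParseError(
                    f"fragment at position {start}: {length} residues declared but "
                    f"file ends after {j}")
            rt = lines[i].split()
            i += 1
            if not rt or rt[0] != "R":
                raise FragmentParseError(
                    f"line {i}: fragment at position {start} declares {length} "
                    f"residues but residue line {j + 1} is missing")
            if len(rt) != 8 + 3 * len(_EXT_ATOMS):
                raise FragmentParseError(
                    f"line {i}: residue line has {len(rt)} fields, expected "
                    f"{8 + 3 * len(_EXT_ATOMS)} (coordinate count mismatch)")
            coords = {}
            vals = [float(x) for x in rt[8:]]
            for k, atom in enumerate(_EXT_ATOMS):
                xyz = np.array(vals[3 * k:3 * k + 3])
                if np.isfinite(xyz).all():
                    coords[atom] = xyz
            residues.append(FragmentResidue(
                aa=rt[1], ss=rt[2],
                phi=_angle_in(rt[3], i), psi=_angle_in(rt[4], i),
                omega=_angle_in(rt[5], i), theta=_angle_in(rt[6], i),
                tau=_angle_in(rt[7], i), coords=coords))
        if i >= len(lines) or lines[i].strip() != "end":
            raise FragmentParseError(f"fragment at position {start}: missing 'end' line")
        i += 1
        frag = Fragment(start_pos=start, residues=residues, pred_rmsd=pred_rmsd,
                        source_id=source)
        if recompute_angles:
            aset = backbone_angles_from_coords(
                frag.atom_array("N"), frag.atom_array("CA"), frag.atom_array("C"))
            for j, r in enumerate(frag.residues):
                r.phi, r.psi, r.omega = aset.phi[j], aset.psi[j], aset.omega[j]
                r.theta, r.tau = aset.theta[j], aset.tau[j]
        positions.setdefault(start, []).append(frag)

    if not positions:
        raise FragmentParseError(f"{path}: no fragments parsed")
    if target_length is None:
        target_length = max(f.end_pos for frs in positions.values() for f in frs)
    return FragmentLibrary(target_length=target_length, positions=positions)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_backbone_pdb(path, chain: str | None = None) -> TargetStructure:
    """Read one chain's backbone (N/CA/C/O/CB ATOM records) from a PDB file.

    AltLocs are resolved by Biopython's default policy (highest occupancy,
    then 'A').  Residues missing any of N/CA/C are skipped with a warning.
    Chain breaks (consecutive CA-CA outside 2.5-4.5 A) are recorded on the
    returned structure and flagged to the log.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure("target", str(path))[0]
    chains = {c.id: c for c in model}
    if chain is None:
        if len(chains) != 1:
            raise ValueError(f"{path}: multiple chains {sorted(chains)}; specify one")
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(f"{path}: chain {chain!r} not present (has {sorted(chains)})")

    seq, N, CA, C, O, CB = [], [], [], [], [], []
    for res in chains[chain]:
        if res.id[0] != " ":
            continue  # HETATM / water
        if not all(a in res for a in ("N", "CA", "C")):
            logger.warning("skipping residue %s: incomplete backbone", res.id)
            continue
        try:
            aa = protein_letters_3to1[res.get_resname()]
        except KeyError:
            aa = "X"
        seq.append(aa)
        N.append(res["N"].get_coord())
        CA.append(res["CA"].get_coord())
        C.append(res["C"].get_coord())
        O.append(res["O"].get_coord() if "O" in res else np.full(3, np.nan))
        CB.append(res["CB"].get_coord() if "CB" in res else None)
    if not seq:
        raise ValueError(f"{path}: chain {chain} has no complete backbone residues")

    N, CA, C, O = (np.asarray(a, float) for a in (N, CA, C, O))
    from .geometry import virtual_cbeta
    cb = np.array([CB[i] if CB[i] is not None else virtual_cbeta(N[i], CA[i], C[i])
                   for i in range(len(seq))])
    return TargetStructure.from_backbone("".join(seq), N, CA, C, O=O, cb=cb)
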