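"""Minimal backbone PDB writer for demo/simulator outputs (internal)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

_AA_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def write_backbone_pdb(structure, path, chain: str = "A") -> Path:
    """Write a TargetStructure's backbone (and CB) as minimal ATOM records."""
    lines = []
    serial = 1
    for i in range(len(structure)):
        resname = _AA_3.get(structure.sequence[i], "UNK")
        atoms = [(a, structure.backbone[a][i]) for a in ("N", "CA", "C", "O")]
        if structure.sequence[i] != "G":
            atoms.append(("CB", structure.cb[i]))
        for name, xyz in atoms:
            if not np.isfinite(xyz).all():
                continue
            pdb_name = f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{resname:>3s} {chain:1s}"
                f"{i + 1:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {_ELEMENT[name]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
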