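"""Readers and writers for every external format the pipeline touches.

Structures (mmCIF/PDB) are parsed with gemmi and normalized into light
per-residue views; predicted-aligned-error matrices come from the JSON
layout written by AlphaFold-style predictors; secondary structure and
solvent accessibility are read from DSSP output files; per-pair results
round-trip through a flat CSV schema.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio.PDB.DSSP import make_dssp_dict

#: Binding-mode flags carried in pair summaries, in column order.
MODE_FLAGS = ("ordered", "idr", "idr_short", "idr_long", "cf",
              "coil_to_order", "disordered")

#: Required pair-summary columns, in order.
SUMMARY_COLUMNS = (
    "pair_id", "protein_a", "protein_b", "iptm", "min_interchain_pae",
    "pdockq", "ilis", "tier", "interface_residues",
) + tuple(f"mode_{f}" for f in MODE_FLAGS)


class StructureIOError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class AtomRecord:
    """One heavy atom with author numbering as found in the file."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise StructureIOError("non-finite atom position")


@dataclass
class ResidueView:
    """A residue with its heavy atoms and pLDDT (1-based chain numbering)."""

    chain_id: str
    residue_index: int
    aa: str
    heavy_atoms: list[AtomRecord]
    plddt: float

    def __post_init__(self) -> None:
        if not self.heavy_atoms:
            raise StructureIOError("residue with no heavy atoms")
        if not 0.0 <= self.plddt <= 100.0:
            raise StructureIOError(
                f"pLDDT {self.plddt} outside [0, 100] "
                f"(chain {self.chain_id} residue {self.residue_index})")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.heavy_atoms])

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.heavy_atoms:
            if a.atom_name == name:
                return a
        return None


def _check_chain(residues: list[ResidueView]) -> None:
    idx = [r.residue_index for r in residues]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise StructureIOError("residue indices not strictly increasing")


@dataclass
class MonomerModel:
    """Single-chain predicted structure, optionally with per-residue SASA."""

    chain: list[ResidueView]
    accessibility: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_chain(self.chain)
        if self.accessibility is not None:
            self.accessibility = np.asarray(self.accessibility, dtype=float)
            if len(self.accessibility) != len(self.chain):
                raise StructureIOError("accessibility length mismatch")
            if np.any(self.accessibility < 0):
                raise StructureIOError("negative accessibility")

    def __len__(self) -> int:
        return len(self.chain)

    @property
    def chain_id(self) -> str:
        return self.chain[0].chain_id

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.chain])

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.chain)


@dataclass
class ComplexModel:
    """Two-chain predicted structure with an aligned PAE matrix.

    Global PAE indices run over chain A residues first (0..len_a-1) then
    chain B (len_a..len_a+len_b-1), matching the AlphaFold layout.
    """

    chain_a: list[ResidueView]
    chain_b: list[ResidueView]
    pae: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.chain_a or not self.chain_b:
            raise StructureIOError("empty chain in complex")
        _check_chain(self.chain_a)
        _check_chain(self.chain_b)
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            n = len(self.chain_a) + len(self.chain_b)
            if self.pae.shape != (n, n):
                raise StructureIOError(
                    f"PAE shape {self.pae.shape} != ({n}, {n})")

    @property
    def chain_id_a(self) -> str:
        return self.chain_a[0].chain_id

    @property
    def chain_id_b(self) -> str:
        return self.chain_b[0].chain_id

    def chain(self, chain_id: str) -> list[ResidueView]:
        if chain_id == self.chain_id_a:
            return self.chain_a
        if chain_id == self.chain_id_b:
            return self.chain_b
        raise KeyError(chain_id)

    def n_residues(self) -> int:
        return len(self.chain_a) + len(self.chain_b)

    def global_index(self, chain_id: str, residue_index: int) -> int:
        """Map (chain, 1-based residue index) to a PAE row/column."""
        chain = self.chain(chain_id)
        if not 1 <= residue_index <= len(chain):
            raise IndexError(f"{chain_id}:{residue_index} out of range")
        off = 0 if chain_id == self.chain_id_a else len(self.chain_a)
        return off + residue_index - 1

    def from_global_index(self, idx: int) -> tuple[str, int]:
        """Inverse of :meth:`global_index`."""
        la = len(self.chain_a)
        if 0 <= idx < la:
            return self.chain_id_a, idx + 1
        if la <= idx < la + len(self.chain_b):
            return self.chain_id_b, idx - la + 1
        raise IndexError(idx)


# ---------------------------------------------------------------------------
# structure reading


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _polymer_chains(structure: gemmi.Structure) -> list[gemmi.Chain]:
    """Chains containing at least one amino-acid residue."""
    chains = []
    for chain in structure[0]:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_amino_acid():
                chains.append(chain)
                break
    return chains


def _chain_residues(chain: gemmi.Chain) -> list[ResidueView]:
    residues = []
    index = 0
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue  # ligands/waters interleaved with the polymer
        atoms = []
        seen = set()
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            if atom.name in seen:  # keep first altloc only
                continue
            seen.add(atom.name)
            atoms.append(AtomRecord(
                chain_id=chain.name,
                residue_index=res.seqid.num,
                residue_name=res.name,
                atom_name=atom.name,
                element=atom.element.name,
                position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            ))
        if not atoms:
            continue
        index += 1
        plddt = float(np.mean([  # AlphaFold writes pLDDT in the B-factor
            a_.b_iso for a_ in res if not a_.element.is_hydrogen]))
        residues.append(ResidueView(
            chain_id=chain.name, residue_index=index,
            aa=_one_letter(res.name), heavy_atoms=atoms, plddt=plddt))
    return residues


def read_structure(path: str | Path,
                   format: str | None = None) -> ComplexModel | MonomerModel:
    """Read an mmCIF or PDB file into a one- or two-chain model.

    Hydrogens are dropped, the first alternate location is kept, and
    per-residue pLDDT is taken as the mean B-factor of the residue's
    heavy atoms.  Files with more than two polymer chains are rejected:
    the pipeline analyzes monomers and dimers only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {None: gemmi.CoorFormat.Detect,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"unreadable structure file {path}: {exc}")
    st.setup_entities()
    chains = _polymer_chains(st)
    if len(chains) == 0:
        raise StructureIOError(f"no polymer chains in {path}")
    if len(chains) > 2:
        raise StructureIOError(
            f"{len(chains)} polymer chains in {path}; dimers only")
    views = [_chain_residues(c) for c in chains]
    if len(views) == 1:
        return MonomerModel(chain=views[0])
    return ComplexModel(chain_a=views[0], chain_b=views[1])


# ---------------------------------------------------------------------------
# PAE matrices

_PAE_KEYS = ("predicted_aligned_error", "pae")


def read_pae(path: str | Path) -> np.ndarray:
    """Read a PAE matrix from AlphaFold-style JSON.

    Entry [i, j] is the expected positional error (Å) of residue j when
    the prediction is aligned on residue i; the matrix is asymmetric.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):  # AlphaFold-DB wraps the object in a list
        if len(data) != 1:
            raise StructureIOError("ambiguous PAE JSON: list of != 1 object")
        data = data[0]
    for key in _PAE_KEYS:
        if key in data:
            matrix = np.asarray(data[key], dtype=float)
            break
    else:
        raise StructureIOError(
            f"no PAE key in {path}; expected one of {_PAE_KEYS}")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise StructureIOError(f"PAE matrix not square: {matrix.shape}")
    if np.any(matrix < 0):
        raise StructureIOError("negative PAE entries")
    return matrix


def write_pae(matrix: np.ndarray, path: str | Path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        json.dump({"predicted_aligned_error": matrix.tolist()}, fh)


# ---------------------------------------------------------------------------
# DSSP output format

@dataclass
class SSResidue:
    """One residue record from a DSSP output file."""

    chain_id: str
    residue_index: int
    aa: str
    ss8: str
    acc: float


def read_ss_record(path: str | Path) -> list[SSResidue]:
    """Read per-residue (8-state secondary structure, accessibility) records.

    Records are returned in file order; chain breaks are preserved as
    chain-id changes and residue-number gaps.
    """
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise StructureIOError(f"malformed DSSP file {path}: {exc}")
    if not keys:
        raise StructureIOError(f"no residue records in DSSP file {path}")
    records = []
    for chain_id, res_id in keys:
        aa, ss, acc = dssp_dict[(chain_id, res_id)][:3]
        records.append(SSResidue(
            chain_id=chain_id, residue_index=res_id[1], aa=aa,
            ss8=" " if ss == "-" else ss, acc=float(acc)))
    return records


def ss8_string(records: list[SSResidue], chain_id: str) -> str:
    return "".join(r.ss8 for r in records if r.chain_id == chain_id)


def acc_array(records: list[SSResidue], chain_id: str) -> np.ndarray:
    return np.array([r.acc for r in records if r.chain_id == chain_id])


_DSSP_HEADER = """\
==== Secondary Structure Definition, generated file ====
REFERENCE
HEADER
COMPND
SOURCE
AUTHOR
{nres:5d}{nchain:3d}    0    0    0 TOTAL NUMBER OF RESIDUES, NUMBER OF CHAINS, NUMBER OF SS-BRIDGES(TOTAL,INTRACHAIN,INTERCHAIN)
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
"""


def write_dssp(chains: list[tuple[str, str, str, np.ndarray]],
               path: str | Path) -> None:
    """Write DSSP-output-format records for one or more chains.

    Parameters
    ----------
    chains
        List of ``(chain_id, sequence, ss8_string, accessibility)``
        tuples; accessibility is absolute, Å², rounded to integers as in
        DSSP output.
    """
    lines = []
    idx = 0
    nres = sum(len(seq) for _, seq, _, _ in chains)
    for ci, (chain_id, seq, ss8, acc) in enumerate(chains):
        if not len(seq) == len(ss8) == len(acc):
            raise ValueError("sequence/ss8/accessibility length mismatch")
        if ci > 0:
            idx += 1
            lines.append(f"{idx:5d}        !*             0   0    0")
        hbond = (f"{0:7d},{0.0:4.1f}" + f"{0:6d},{0.0:4.1f}" * 3)
        for i, (aa, ss, a) in enumerate(zip(seq, ss8, acc)):
            idx += 1
            # fixed columns: aa at 13, ss at 16, acc at 34:38, H-bond
            # fields at 38:83, phi/psi at 103:115
            line = (f"{idx:5d}{i + 1:5d} {chain_id}{aa:>2s}  {ss:1s}"
                    + " " * 17
                    + f"{int(round(a)):4d}"
                    + hbond
                    + " " * 20
                    + f"{360.0:6.1f}{360.0:6.1f}")
            lines.append(line)
    with open(path, "w") as fh:
        fh.write(_DSSP_HEADER.format(nres=nres, nchain=len(chains)))
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pair summaries

def format_interface_spans(spans: dict[str, list[tuple[int, int]]]) -> str:
    """Serialize interface spans as ``"A:100-112;B:46-104"``."""
    parts = []
    for chain_id in sorted(spans):
        for start, end in spans[chain_id]:
            parts.append(f"{chain_id}:{start}-{end}")
    return ";".join(parts)


def parse_interface_spans(text: str) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    if not text or (isinstance(text, float) and math.isnan(text)):
        return spans
    for part in str(text).split(";"):
        chain_id, rng = part.split(":")
        start, end = rng.split("-")
        spans.setdefault(chain_id, []).append((int(start), int(end)))
    return spans


def write_pair_summary(records, path: str | Path) -> None:
    """Write per-pair results to CSV (UTF-8, header row).

    ``records`` may be a DataFrame or a list of dicts.  Required columns
    are created (empty) if absent; unknown columns are preserved after
    the required ones.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=object)
    extra = [c for c in df.columns if c not in SUMMARY_COLUMNS]
    df = df[list(SUMMARY_COLUMNS) + extra]
    df.to_csv(path, index=False)


def read_pair_summary(path: str | Path) -> pd.DataFrame:
    """Read a pair-summary CSV; unknown columns are preserved opaquely."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise StructureIOError(f"empty pair-summary file {path}")
    if "pdockq" not in df.columns:
        raise StructureIOError("pair summary lacks a 'pdockq' column")
    has_pair = "pair_id" in df.columns
    has_proteins = {"protein_a", "protein_b"} <= set(df.columns)
    if not (has_pair or has_proteins):
        raise StructureIOError(
            "pair summary needs 'pair_id' or 'protein_a'/'protein_b'")
    if has_pair and not has_proteins:
        ab = df["pair_id"].astype(str).str.split("__", expand=True)
        if ab.shape[1] == 2:
            df["protein_a"], df["protein_b"] = ab[0], ab[1]
    if not has_pair and has_proteins:
        df["pair_id"] = (df["protein_a"].astype(str) + "__"
                         + df["protein_b"].astype(str))
    return df
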