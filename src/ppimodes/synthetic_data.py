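"""Self-contained toy fixtures with designed ground truth.

Two kinds of fixtures are generated: toy dimer structures whose interface
blocks carry designed binding modes (ordered, disordered, coil-to-order,
conditionally folded), and pair-summary tables whose high-confidence
subgraph has a prescribed component structure.  Everything the pipeline
consumes — mmCIF coordinates with pLDDT in the B-factor field, PAE JSON,
DSSP-format secondary structure and accessibility — can be written to
disk through the structure_io writers, so every stage is testable without
downloads.

Geometry is idealized: residues are poly-alanine beads spaced 3.8 Å along
the chain axis, and interface blocks are realized as parallel traces whose
atom clouds sit 6.3 Å apart.  That gap is chosen so that directly opposed
residues are within the 7 Å heavy-atom contact cutoff while diagonal
neighbours (offset one residue, 3.8 Å along the chain) are just outside
it, which makes designed interface spans recover exactly.  Non-interface
residues are kept > 12 Å from the partner chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .monomer_annotation import MAX_ACC
from .structure_io import (AtomRecord, ComplexModel, MonomerModel,
                           ResidueView, write_dssp, write_pae)

#: Modes a designed interface block may carry.
DESIGNED_MODES = ("ordered", "disordered", "coil_to_order", "cf")

# Expected region-level flags for each designed mode (idr_short/idr_long
# depends on block length and is added at build time).
_MODE_FLAGS = {
    "ordered": {"ordered"},
    "disordered": {"idr", "disordered"},
    "coil_to_order": {"idr", "coil_to_order"},
    "cf": {"idr", "cf"},
}

# Per-atom offsets (dy, dz) from the CA position; dy is the direction
# facing the partner chain.  All atoms of a residue share one x.
_ATOM_OFFSETS = {
    "N": (0.0, 1.2), "CA": (0.0, 0.0), "C": (0.0, -1.2),
    "O": (0.4, -2.0), "CB": (0.5, 0.8),
}
_SPACING = 3.8     # Å between consecutive residues along the chain
_GAP_CA = 7.3      # CA-CA separation across a designed interface
_FAR_Y = 40.0      # partner-chain distance for non-interface residues


@dataclass(frozen=True)
class InterfaceBlock:
    """One designed interface: aligned spans on both chains, one mode."""

    span_a: tuple[int, int]
    span_b: tuple[int, int]
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in DESIGNED_MODES:
            raise ValueError(f"unknown designed mode {self.mode!r}")
        for s, e in (self.span_a, self.span_b):
            if s > e:
                raise ValueError("block span start > end")
        if (self.span_a[1] - self.span_a[0]
                != self.span_b[1] - self.span_b[0]):
            raise ValueError("span_a and span_b must have equal length; "
                             "blocks are realized as 1:1 aligned traces")

    def __len__(self) -> int:
        return self.span_a[1] - self.span_a[0] + 1


@dataclass
class ToyDimerSpec:
    """Design of a toy dimer.

    Defaults put pLDDT and ISD well clear of the 70 / 0.5 thresholds
    (margins >= 0.3 on ISD, >= 15 on pLDDT even after the ±2 pLDDT
    noise), so classification is never knife-edge.
    """

    len_a: int = 120
    len_b: int = 120
    interface_blocks: list[InterfaceBlock] = field(default_factory=list)
    plddt_ordered: float = 90.0
    plddt_disordered: float = 45.0
    isd_high: float = 0.9
    isd_low: float = 0.1
    pae_low: float = 5.0
    pae_high: float = 25.0
    pae_intra: float = 3.0
    plddt_noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        # clean-margin constraints: designed disorder must survive the
        # window-25 ISD smoothing with its exact span, and neighbouring
        # blocks must not merge into one interface region
        for which, length in (("a", self.len_a), ("b", self.len_b)):
            spans = sorted((getattr(b, f"span_{which}"), b.mode)
                           for b in self.interface_blocks)
            for (s, e), mode in spans:
                if not 1 <= s <= e <= length:
                    raise ValueError(f"span {s}-{e} outside chain {which}")
                if mode != "ordered" and e - s + 1 < 13:
                    raise ValueError(
                        "disorder-carrying blocks need >= 13 residues to "
                        "survive window-25 ISD smoothing exactly")
                if mode != "ordered" and not (
                        (s == 1 or s >= 14)
                        and (e == length or e <= length - 13)):
                    raise ValueError(
                        "disorder-carrying block edges must lie at the "
                        "terminus or >= 13 residues from it; otherwise the "
                        "shrinking ISD window smears the designed span")
            for ((_, e1), m1), ((s2, _), m2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError("overlapping interface blocks")
                gap = s2 - e1 - 1
                need = 13 if (m1 != "ordered" and m2 != "ordered") else 3
                if gap < need:
                    raise ValueError(
                        f"blocks separated by {gap} residues would merge; "
                        f"need >= {need}")
        if not (self.pae_low < 15.0 < self.pae_high):
            raise ValueError("need pae_low < 15 < pae_high")


@dataclass
class ToyDimerTruth:
    """Designed ground truth attached to a generated dimer."""

    blocks: list[InterfaceBlock]
    region_flags: list[set[str]]          # per block, either chain
    ppi_flags: set[str]
    interface_spans_a: list[tuple[int, int]]
    interface_spans_b: list[tuple[int, int]]


@dataclass
class ToyDimer:
    """A generated dimer plus every input file the pipeline needs."""

    complex_model: ComplexModel
    monomer_a: MonomerModel
    monomer_b: MonomerModel
    monomer_ss8_a: str
    monomer_ss8_b: str
    complex_ss8_a: str
    complex_ss8_b: str
    pae: np.ndarray
    truth: ToyDimerTruth
    spec: ToyDimerSpec

    def write_fixture(self, directory: str | Path,
                      prefix: str = "pair") -> dict[str, str]:
        """Write all files for one pair; returns a manifest row."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "complex": directory / f"{prefix}_complex.cif",
            "monomer_a": directory / f"{prefix}_monomer_a.cif",
            "monomer_b": directory / f"{prefix}_monomer_b.cif",
            "pae": directory / f"{prefix}_pae.json",
            "dssp_monomer_a": directory / f"{prefix}_monomer_a.dssp",
            "dssp_monomer_b": directory / f"{prefix}_monomer_b.dssp",
            "dssp_complex": directory / f"{prefix}_complex.dssp",
        }
        write_mmcif([("A", self.complex_model.chain_a),
                     ("B", self.complex_model.chain_b)], paths["complex"])
        write_mmcif([("A", self.monomer_a.chain)], paths["monomer_a"])
        write_mmcif([("B", self.monomer_b.chain)], paths["monomer_b"])
        write_pae(self.pae, paths["pae"])
        acc_a = self.monomer_a.accessibility
        acc_b = self.monomer_b.accessibility
        seq_a = self.monomer_a.sequence
        seq_b = self.monomer_b.sequence
        write_dssp([("A", seq_a, self.monomer_ss8_a, acc_a)],
                   paths["dssp_monomer_a"])
        write_dssp([("B", seq_b, self.monomer_ss8_b, acc_b)],
                   paths["dssp_monomer_b"])
        write_dssp([("A", seq_a, self.complex_ss8_a, np.zeros(len(seq_a))),
                    ("B", seq_b, self.complex_ss8_b, np.zeros(len(seq_b)))],
                   paths["dssp_complex"])
        return {k: str(v) for k, v in paths.items()}


def _residue(chain_id: str, index: int, x: float, y_base: float,
             toward: float, plddt: float) -> ResidueView:
    atoms = []
    for name, (dy, dz) in _ATOM_OFFSETS.items():
        atoms.append(AtomRecord(
            chain_id=chain_id, residue_index=index, residue_name="ALA",
            atom_name=name, element="C" if name.startswith("C") else name[0],
            position=np.array([x, y_base + toward * dy, dz])))
    return ResidueView(chain_id=chain_id, residue_index=index, aa="A",
                       heavy_atoms=atoms, plddt=plddt)


def _design_tracks(length: int, blocks, which: str, spec: ToyDimerSpec,
                   rng: np.random.Generator):
    """Per-residue pLDDT, target ISD, monomer ss8 and complex ss8."""
    plddt = np.full(length, spec.plddt_ordered)
    isd = np.full(length, spec.isd_low)
    mono_ss8 = ["H"] * length
    cplx_ss8 = ["H"] * length
    for block in blocks:
        s, e = getattr(block, f"span_{which}")
        sl = slice(s - 1, e)
        if block.mode in ("disordered", "coil_to_order", "cf"):
            isd[sl] = spec.isd_high
        if block.mode in ("disordered", "coil_to_order"):
            plddt[sl] = spec.plddt_disordered
            mono_ss8[sl] = [" "] * (e - s + 1)
            cplx_ss8[sl] = ([" "] if block.mode == "disordered"
                            else ["E"]) * (e - s + 1)
    noise = rng.uniform(-spec.plddt_noise, spec.plddt_noise, size=length)
    plddt = np.clip(plddt + noise, 0.0, 100.0)
    return plddt, isd, "".join(mono_ss8), "".join(cplx_ss8)


def make_toy_dimer(spec: ToyDimerSpec) -> ToyDimer:
    """Realize a :class:`ToyDimerSpec` into structures, tracks and truth.

    Deterministic under ``spec.seed``.  Designed ISD is encoded as DSSP-style
    absolute accessibility (ISD × max-accessibility of alanine), so the
    pipeline's windowed-RSA disorder score reproduces the design.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = sorted(spec.interface_blocks, key=lambda b: b.span_a)
    plddt_a, isd_a, mono8_a, cplx8_a = _design_tracks(
        spec.len_a, blocks, "a", spec, rng)
    plddt_b, isd_b, mono8_b, cplx8_b = _design_tracks(
        spec.len_b, blocks, "b", spec, rng)

    # chain A along x at y = 0; chain B opposite designed blocks at the
    # contact gap, far away elsewhere
    aligned_x = {}
    for block in blocks:
        (sa, _), (sb, eb) = block.span_a, block.span_b
        for k in range(eb - sb + 1):
            aligned_x[sb + k] = _SPACING * (sa + k)
    chain_a = [_residue("A", i, _SPACING * i, 0.0, +1.0, plddt_a[i - 1])
               for i in range(1, spec.len_a + 1)]
    chain_b = []
    for j in range(1, spec.len_b + 1):
        if j in aligned_x:
            chain_b.append(_residue("B", j, aligned_x[j], _GAP_CA, -1.0,
                                    plddt_b[j - 1]))
        else:
            chain_b.append(_residue("B", j, _SPACING * j, _FAR_Y, -1.0,
                                    plddt_b[j - 1]))

    n = spec.len_a + spec.len_b
    pae = np.full((n, n), spec.pae_intra)
    pae[:spec.len_a, spec.len_a:] = spec.pae_high
    pae[spec.len_a:, :spec.len_a] = spec.pae_high
    for block in blocks:
        (sa, ea), (sb, eb) = block.span_a, block.span_b
        rows = slice(sa - 1, ea)
        cols = slice(spec.len_a + sb - 1, spec.len_a + eb)
        pae[rows, cols] = spec.pae_low
        pae[cols, rows] = spec.pae_low

    complex_model = ComplexModel(chain_a=chain_a, chain_b=chain_b, pae=pae)
    acc_a = np.round(isd_a * MAX_ACC["A"])
    acc_b = np.round(isd_b * MAX_ACC["A"])
    monomer_a = MonomerModel(chain=[_residue("A", i, _SPACING * i, 0.0, 1.0,
                                             plddt_a[i - 1])
                                    for i in range(1, spec.len_a + 1)],
                             accessibility=acc_a)
    monomer_b = MonomerModel(chain=[_residue("B", j, _SPACING * j, 0.0, 1.0,
                                             plddt_b[j - 1])
                                    for j in range(1, spec.len_b + 1)],
                             accessibility=acc_b)

    region_flags = []
    ppi_flags: set[str] = set()
    for block in blocks:
        flags = set(_MODE_FLAGS[block.mode])
        if "idr" in flags:
            flags.add("idr_long" if len(block) >= 30 else "idr_short")
        region_flags.append(flags)
        ppi_flags |= flags - {"disordered"}
    truth = ToyDimerTruth(
        blocks=blocks, region_flags=region_flags, ppi_flags=ppi_flags,
        interface_spans_a=[b.span_a for b in blocks],
        interface_spans_b=sorted(b.span_b for b in blocks))
    return ToyDimer(complex_model=complex_model, monomer_a=monomer_a,
                    monomer_b=monomer_b, monomer_ss8_a=mono8_a,
                    monomer_ss8_b=mono8_b, complex_ss8_a=cplx8_a,
                    complex_ss8_b=cplx8_b, pae=pae, truth=truth, spec=spec)


def write_mmcif(chains: list[tuple[str, list[ResidueView]]],
                path: str | Path) -> None:
    """Write chains of ResidueViews to mmCIF via gemmi (pLDDT -> B-factor)."""
    st = gemmi.Structure()
    st.name = Path(path).stem
    model = gemmi.Model(1)
    for chain_id, residues in chains:
        chain = gemmi.Chain(chain_id)
        for res in residues:
            r = gemmi.Residue()
            r.name = "ALA" if res.aa == "A" else res.heavy_atoms[0].residue_name
            r.seqid = gemmi.SeqId(res.residue_index, " ")
            for atom in res.heavy_atoms:
                a = gemmi.Atom()
                a.name = atom.atom_name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.position)
                a.b_iso = res.plddt
                a.occ = 1.0
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# pair-summary fixtures with prescribed network structure

@dataclass
class SummaryFixtureSpec:
    """Design of a pair-summary table for network-stage tests."""

    component_edge_counts: list[int] = field(default_factory=lambda: [5, 3])
    n_singletons: int = 2
    pdockq_range: tuple[float, float] = (0.55, 0.95)
    n_decoys: int = 5
    decoy_pdockq: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.component_edge_counts):
            raise ValueError("component edge counts must be >= 1")
        if self.n_singletons < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.pdockq_range
        if not 0.5 <= lo <= hi <= 1.0:
            raise ValueError("pdockq_range must lie within [0.5, 1.0] so "
                             "designed edges are high-confidence")


def make_summary_fixture(spec: SummaryFixtureSpec) -> pd.DataFrame:
    """Pair-summary table whose high-confidence subgraph is prescribed.

    Each requested component is realized as a path (a tree with exactly
    the requested edge count); singletons are isolated one-edge pairs;
    decoy rows sit below the acceptable threshold and never enter the
    graph.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pdockq_range
    rows = []

    def add_row(a: str, b: str, pdockq: float) -> None:
        rows.append({
            "pair_id": f"{a}__{b}", "protein_a": a, "protein_b": b,
            "iptm": round(float(rng.uniform(0.2, 0.95)), 3),
            "min_interchain_pae": round(float(rng.uniform(1.0, 30.0)), 2),
            "pdockq": round(pdockq, 4), "ilis": "",
        })

    for ci, n_edges in enumerate(spec.component_edge_counts):
        names = [f"C{ci:02d}N{k:03d}" for k in range(n_edges + 1)]
        for a, b in zip(names, names[1:]):
            add_row(a, b, float(rng.uniform(lo, hi)))
    for si in range(spec.n_singletons):
        add_row(f"S{si:03d}a", f"S{si:03d}b", float(rng.uniform(lo, hi)))
    for di in range(spec.n_decoys):
        add_row(f"D{di:03d}a", f"D{di:03d}b", spec.decoy_pdockq)
    df = pd.DataFrame(rows)
    df["tier"] = np.where(df["pdockq"] >= 0.5, "high", "low")
    return df
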