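"""Inter-chain contact detection and interface-region merging.

Two residues on different chains interact if any pair of their heavy
(non-hydrogen) atoms is within 7 Å.  Contacts whose predicted aligned
error exceeds 15 Å are discarded as geometrically unreliable, and the
surviving interface residues on each chain are merged into contiguous
regions, absorbing gaps of fewer than 3 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .monomer_annotation import Region, segment_true_runs
from .structure_io import ComplexModel


@dataclass(frozen=True)
class ContactPair:
    """An inter-chain residue pair within the contact cutoff."""

    res_a: tuple[str, int]
    res_b: tuple[str, int]
    min_heavy_distance: float
    pae_value: float | None = None


@dataclass
class InterfaceRegion:
    """A merged span of interface residues on one chain."""

    chain: str
    span: Region
    member_residues: list[int]
    partner_spans: list[Region] = field(default_factory=list)
    contacts: list[ContactPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.member_residues = sorted(self.member_residues)
        if self.member_residues:
            if (self.member_residues[0] < self.span.start
                    or self.member_residues[-1] > self.span.end):
                raise ValueError("member residues outside region span")


def find_contacts(complex_model: ComplexModel,
                  cutoff: float = 7.0) -> list[ContactPair]:
    """All inter-chain residue pairs with minimal heavy-atom distance <= cutoff.

    Uses a k-d tree over chain B atoms; results are identical to the
    all-pairs distance scan.
    """
    if not complex_model.chain_a or not complex_model.chain_b:
        raise ValueError("empty chain")
    coords_b, owner_b = [], []
    for res in complex_model.chain_b:
        for atom in res.heavy_atoms:
            coords_b.append(atom.position)
            owner_b.append(res.residue_index)
    coords_b = np.asarray(coords_b)
    owner_b = np.asarray(owner_b)
    tree = cKDTree(coords_b)
    best: dict[tuple[int, int], float] = {}
    for res in complex_model.chain_a:
        coords_a = res.coords()
        for atom_xyz, hits in zip(coords_a,
                                  tree.query_ball_point(coords_a, cutoff)):
            if not hits:
                continue
            dists = np.linalg.norm(coords_b[hits] - atom_xyz, axis=1)
            for j, dist in zip(hits, dists):
                key = (res.residue_index, int(owner_b[j]))
                if dist <= cutoff and dist < best.get(key, np.inf):
                    best[key] = float(dist)
    ca, cb = complex_model.chain_id_a, complex_model.chain_id_b
    return [ContactPair(res_a=(ca, ia), res_b=(cb, ib),
                        min_heavy_distance=dist)
            for (ia, ib), dist in sorted(best.items())]


def filter_contacts_by_pae(contacts: list[ContactPair],
                           complex_model: ComplexModel,
                           max_pae: float = 15.0,
                           combine: str = "mean") -> list[ContactPair]:
    """Keep contacts whose symmetrized PAE does not exceed ``max_pae``.

    The PAE matrix is asymmetric; the two directional entries for a
    residue pair are combined by ``mean`` (default), ``min`` or ``max``.
    Exclusion requires the combined value to be strictly greater than
    the cutoff, so a boundary value of exactly ``max_pae`` is retained.
    """
    if complex_model.pae is None:
        raise ValueError("complex has no PAE matrix attached")
    comb = {"mean": lambda a, b: (a + b) / 2.0,
            "min": min, "max": max}[combine]
    pae = complex_model.pae
    kept = []
    for c in contacts:
        i = complex_model.global_index(*c.res_a)
        j = complex_model.global_index(*c.res_b)
        value = comb(float(pae[i, j]), float(pae[j, i]))
        if value <= max_pae:
            kept.append(ContactPair(res_a=c.res_a, res_b=c.res_b,
                                    min_heavy_distance=c.min_heavy_distance,
                                    pae_value=value))
    return kept


def build_interface_regions(contacts: list[ContactPair],
                            chain: str,
                            max_gap: int = 2) -> list[InterfaceRegion]:
    """Group one chain's interface residues into merged regions.

    Residue runs separated by fewer than 3 residues (gap <= ``max_gap``)
    are contiguous; each region records its own member residues, its
    contacts, and the partner-chain spans obtained by applying the same
    grouping to the region's partner residues.
    """
    mine: dict[int, list[ContactPair]] = {}
    for c in contacts:
        if c.res_a[0] == chain:
            mine.setdefault(c.res_a[1], []).append(c)
        elif c.res_b[0] == chain:
            mine.setdefault(c.res_b[1], []).append(c)
    if not mine:
        return []
    residues = sorted(mine)
    n = residues[-1]
    mask = np.zeros(n, dtype=bool)
    mask[np.array(residues) - 1] = True
    regions = []
    for span in segment_true_runs(mask, min_len=1, max_gap=max_gap,
                                  kind="interface"):
        members = [r for r in residues if span.contains(r)]
        cts = [c for r in members for c in mine[r]]
        partners = sorted({(c.res_b if c.res_a[0] == chain else c.res_a)[1]
                           for c in cts})
        pmask = np.zeros(partners[-1], dtype=bool)
        pmask[np.array(partners) - 1] = True
        partner_spans = segment_true_runs(pmask, min_len=1, max_gap=max_gap,
                                          kind="interface")
        regions.append(InterfaceRegion(chain=chain, span=span,
                                       member_residues=members,
                                       partner_spans=partner_spans,
                                       contacts=cts))
    return regions
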