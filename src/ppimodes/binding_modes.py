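"""Binding-mode classification of interface regions and whole PPIs.

Each interface region is flagged, non-exclusively, as ordered (overlaps
an ordered region of the monomer), IDR (overlaps an intrinsically
disordered region; short/long by the IDR's kind), conditionally folded
(overlaps a CF region), and/or coil-to-order (its helix+strand content
rises significantly from the monomer to the complex, one-sided Fisher
exact test at alpha 0.05).  "Disordered" is the residual IDR mode: an
IDR interface that is neither CF nor coil-to-order.  A PPI inherits the
union of its regions' flags — the modes are not mutually exclusive
within one interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import fisher_exact

from .config import PipelineConfig
from .interface_detection import InterfaceRegion
from .monomer_annotation import MonomerAnnotation

ALL_FLAGS = ("ordered", "idr", "idr_short", "idr_long", "cf",
             "coil_to_order", "disordered")

PPI_FLAGS = ("ordered", "idr", "idr_short", "idr_long", "cf",
             "coil_to_order")


@dataclass
class Contingency2x2:
    """Ordered-vs-coil residue counts of one region, complex vs monomer."""

    complex_ordered: int
    complex_coil: int
    monomer_ordered: int
    monomer_coil: int

    def __post_init__(self) -> None:
        counts = (self.complex_ordered, self.complex_coil,
                  self.monomer_ordered, self.monomer_coil)
        if any(c < 0 for c in counts):
            raise ValueError("negative contingency counts")
        if (self.complex_ordered + self.complex_coil
                != self.monomer_ordered + self.monomer_coil):
            raise ValueError("complex and monomer rows cover different "
                             "numbers of residues")


@dataclass
class RegionModeAnnotation:
    region: InterfaceRegion
    flags: set[str] = field(default_factory=set)
    fisher_p: float | None = None


@dataclass
class PPIModeSummary:
    pair_id: str
    flags: set[str] = field(default_factory=set)


def fisher_one_sided_greater(table: Contingency2x2) -> float:
    """One-sided Fisher exact p: is the complex row more ordered-enriched?

    The exact hypergeometric tail probability that, with the observed
    margins fixed, the complex row contains at least as many ordered
    residues as observed.  Degenerate tables (a zero row or column
    margin) carry no evidence and return 1.0.
    """
    _, p = fisher_exact(
        [[table.complex_ordered, table.complex_coil],
         [table.monomer_ordered, table.monomer_coil]],
        alternative="greater")
    return min(float(p), 1.0)


def _ordered_count(ss3: str, residues: list[int]) -> int:
    return sum(1 for r in residues if ss3[r - 1] in "HE")


def detect_coil_to_order(region: InterfaceRegion, monomer_ss3: str,
                         complex_ss3: str,
                         alpha: float = 0.05) -> tuple[bool, float]:
    """Test one interface region for a coil-to-order transition.

    Counts helix+strand residues among the region's member residues in
    the monomer and complex secondary-structure strings; significant
    (p < alpha) *and* strictly greater ordered fraction in the complex
    is required, so a region already fully ordered in the monomer can
    never be called coil-to-order.
    """
    members = region.member_residues
    if region.span.end > len(monomer_ss3) or region.span.end > len(complex_ss3):
        raise ValueError("region span outside secondary-structure string")
    n = len(members)
    co = _ordered_count(complex_ss3, members)
    mo = _ordered_count(monomer_ss3, members)
    table = Contingency2x2(complex_ordered=co, complex_coil=n - co,
                           monomer_ordered=mo, monomer_coil=n - mo)
    p = fisher_one_sided_greater(table)
    return (p < alpha and co > mo), p


def _overlaps_any(region: InterfaceRegion, annotation_regions) -> bool:
    return any(ann.start <= r <= ann.end
               for ann in annotation_regions
               for r in region.member_residues)


def classify_interface_region(region: InterfaceRegion,
                              annotation: MonomerAnnotation,
                              complex_ss3: str,
                              params: PipelineConfig | None = None,
                              ) -> RegionModeAnnotation:
    """Assign non-exclusive mode flags to one interface region."""
    params = params or PipelineConfig()
    flags: set[str] = set()
    fisher_p = None
    if _overlaps_any(region, annotation.ordered_regions):
        flags.add("ordered")
    for idr in annotation.idr_regions:
        if any(idr.contains(r) for r in region.member_residues):
            flags.add("idr")
            flags.add(idr.kind)  # idr_short or idr_long
    if _overlaps_any(region, annotation.cf_regions):
        flags.add("cf")
    if _overlaps_any(region, annotation.coil_regions):
        c2o, fisher_p = detect_coil_to_order(
            region, annotation.ss3, complex_ss3, alpha=params.fisher_alpha)
        if c2o:
            flags.add("coil_to_order")
    if "idr" in flags and not flags & {"cf", "coil_to_order"}:
        flags.add("disordered")
    return RegionModeAnnotation(region=region, flags=flags, fisher_p=fisher_p)


def aggregate_ppi_modes(regions_both_chains: list[RegionModeAnnotation],
                        pair_id: str = "") -> PPIModeSummary:
    """OR-reduce region flags across both chains into one PPI summary.

    The residual per-region "disordered" flag is not carried at the PPI
    level; the PPI vocabulary follows the network-wide mode counts
    (ordered, idr, idr_short, idr_long, cf, coil_to_order).
    """
    flags: set[str] = set()
    for ann in regions_both_chains:
        flags |= ann.flags
    return PPIModeSummary(pair_id=pair_id, flags=flags & set(PPI_FLAGS))
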