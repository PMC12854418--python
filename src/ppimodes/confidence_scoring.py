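"""pDockQ, minimal inter-chain PAE, and confidence tiers.

pDockQ scores a predicted dimer from its own prediction quality signals:

    pDockQ = L / (1 + exp(-k (x - x0))) + b,
    x = <pLDDT over interface residues> * ln(n interface contacts)

with the published constants L = 0.724, x0 = 152.611, k = 0.052,
b = 0.018.  The pDockQ interface is Cb-Cb (Ca for glycine) pairs within
8 Å — deliberately distinct from the 7 Å heavy-atom interface used for
binding-mode analysis.  Pairs are tiered: high (pDockQ >= 0.5),
acceptable (>= 0.23), possible (ipTM >= 0.5 or minimal inter-chain
PAE <= 10 Å), else low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .structure_io import ComplexModel, ResidueView


@dataclass(frozen=True)
class PDockQParams:
    """Sigmoid constants from the pDockQ publication (config-exposed)."""

    L: float = 0.724
    x0: float = 152.611
    k: float = 0.052
    b: float = 0.018


@dataclass
class ConfidenceSummary:
    pdockq: float
    iptm: float
    min_interchain_pae: float
    n_if_contacts: int
    mean_if_plddt: float
    tier: str = ""


def _cb_or_ca(res: ResidueView) -> np.ndarray:
    name = "CA" if res.aa == "G" else "CB"
    atom = res.atom(name) or (res.atom("CA") if name == "CB" else None)
    if atom is None:
        raise ValueError(
            f"residue {res.chain_id}:{res.residue_index} lacks CB/CA")
    return atom.position


def compute_pdockq(complex_model: ComplexModel,
                   params: PDockQParams | None = None,
                   cutoff: float = 8.0) -> tuple[float, int, float]:
    """pDockQ for a two-chain model.

    Returns ``(pdockq, n_if_contacts, mean_if_plddt)``.  Interface
    contacts are Cb-Cb (Ca for glycine) residue pairs within ``cutoff``;
    with zero contacts pDockQ is defined as 0.
    """
    params = params or PDockQParams()
    xyz_a = np.array([_cb_or_ca(r) for r in complex_model.chain_a])
    xyz_b = np.array([_cb_or_ca(r) for r in complex_model.chain_b])
    d2 = np.sum((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2, axis=2)
    ia, ib = np.nonzero(d2 <= cutoff ** 2)
    n_contacts = len(ia)
    if n_contacts == 0:
        return 0.0, 0, 0.0
    plddt_a = np.array([r.plddt for r in complex_model.chain_a])
    plddt_b = np.array([r.plddt for r in complex_model.chain_b])
    mean_plddt = float(np.concatenate([plddt_a[np.unique(ia)],
                                       plddt_b[np.unique(ib)]]).mean())
    x = mean_plddt * math.log(n_contacts)
    pdockq = params.L / (1 + math.exp(-params.k * (x - params.x0))) + params.b
    return float(pdockq), n_contacts, mean_plddt


def min_interchain_pae(pae: np.ndarray, len_a: int) -> float:
    """Minimum PAE over inter-chain entries, both directions."""
    pae = np.asarray(pae, dtype=float)
    n = pae.shape[0]
    if not 0 < len_a < n:
        raise ValueError("chain split leaves an empty chain")
    return float(min(pae[:len_a, len_a:].min(), pae[len_a:, :len_a].min()))


def assign_tier(summary: ConfidenceSummary,
                thresholds: PipelineConfig | None = None) -> str:
    """Assign high / acceptable / possible / low.

    The "possible" tier combines the ipTM and minimal-PAE conditions with
    OR by default (``thresholds.possible_combiner``); ipTM is held on
    [0, 1], so a percent-style cutoff of 50 corresponds to 0.5.
    """
    t = thresholds or PipelineConfig()
    if summary.pdockq >= t.pdockq_high:
        return "high"
    if summary.pdockq >= t.pdockq_acceptable:
        return "acceptable"
    ok_iptm = summary.iptm >= t.iptm_possible
    ok_pae = summary.min_interchain_pae <= t.pae_possible
    possible = (ok_iptm or ok_pae) if t.possible_combiner == "or" \
        else (ok_iptm and ok_pae)
    return "possible" if possible else "low"


def score_complex(complex_model: ComplexModel, iptm: float = 0.0,
                  thresholds: PipelineConfig | None = None,
                  params: PDockQParams | None = None) -> ConfidenceSummary:
    """Full confidence summary (pDockQ, min inter-chain PAE, tier)."""
    pdockq, n_contacts, mean_plddt = compute_pdockq(complex_model, params)
    if complex_model.pae is None:
        raise ValueError("complex has no PAE matrix attached")
    mpae = min_interchain_pae(complex_model.pae, len(complex_model.chain_a))
    summary = ConfidenceSummary(pdockq=pdockq, iptm=iptm,
                                min_interchain_pae=mpae,
                                n_if_contacts=n_contacts,
                                mean_if_plddt=mean_plddt)
    summary.tier = assign_tier(summary, thresholds)
    return summary
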