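"""Pipeline-wide thresholds and parameters.

Every numeric cutoff used anywhere in the pipeline lives here, so a run can
be reproduced from a single config file.  Defaults are the values used for
the genome-scale analysis this package re-implements: 7 Å heavy-atom
contacts, 15 Å PAE exclusion, gap-2 region merging, ISD > 0.5 disorder,
pLDDT > 70 conditional folding, minimum region length 5, long-IDR length 30,
Fisher alpha 0.05, and the pDockQ 0.5 / 0.23 confidence tiers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Bag of thresholds shared by all pipeline stages.

    Attributes
    ----------
    contact_cutoff : float
        Maximum heavy-atom distance (Å) for two residues on different
        chains to count as interacting.
    pae_exclude : float
        Contacts whose symmetrized predicted aligned error exceeds this
        value (Å) are discarded as unreliable.
    merge_gap : int
        Interface/disorder runs separated by at most this many residues
        are merged into one region.
    isd_threshold : float
        Per-residue intrinsic structural disorder above this value marks
        a residue as disordered.
    plddt_cf : float
        pLDDT above this value, together with high ISD, marks a residue
        as conditionally folded.
    min_region : int
        Minimum region length (residues) after gap bridging.
    long_idr : int
        Disordered regions at least this long are "long" IDRs.
    fisher_alpha : float
        One-sided Fisher p-value cutoff for coil-to-order calls.
    pdockq_high, pdockq_acceptable : float
        pDockQ tier thresholds.
    iptm_possible : float
        ipTM (on [0, 1]) threshold for the "possible" tier.
    pae_possible : float
        Minimal inter-chain PAE (Å) threshold for the "possible" tier.
    possible_combiner : str
        "or" (default) or "and": how ipTM and PAE conditions combine for
        the "possible" tier.
    isd_variant : str
        "rsa_window" (windowed relative solvent accessibility, default) or
        "plddt_window" (windowed 1 - pLDDT/100).
    isd_window : int
        Odd window length (residues) for ISD smoothing.
    pae_combine : str
        How the two directional PAE entries are symmetrized per contact:
        "mean" (default), "min" or "max".
    mcl_inflation : float
        Markov-clustering inflation parameter.
    seed : int
        Seed for every stochastic step (permutation test, fixtures).
    """

    contact_cutoff: float = 7.0
    pae_exclude: float = 15.0
    merge_gap: int = 2
    isd_threshold: float = 0.5
    plddt_cf: float = 70.0
    min_region: int = 5
    long_idr: int = 30
    fisher_alpha: float = 0.05
    pdockq_high: float = 0.5
    pdockq_acceptable: float = 0.23
    iptm_possible: float = 0.5
    pae_possible: float = 10.0
    possible_combiner: str = "or"
    isd_variant: str = "rsa_window"
    isd_window: int = 25
    pae_combine: str = "mean"
    mcl_inflation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pdockq_high < self.pdockq_acceptable:
            raise ValueError("pdockq_high must be >= pdockq_acceptable")
        for name in ("contact_cutoff", "pae_exclude", "isd_threshold",
                     "plddt_cf", "fisher_alpha", "pdockq_high",
                     "pdockq_acceptable", "iptm_possible", "pae_possible"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.possible_combiner not in ("or", "and"):
            raise ValueError("possible_combiner must be 'or' or 'and'")
        if self.pae_combine not in ("mean", "min", "max"):
            raise ValueError("pae_combine must be 'mean', 'min' or 'max'")
        if self.isd_window % 2 == 0:
            raise ValueError("isd_window must be odd")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML file of ``field: value`` pairs."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
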