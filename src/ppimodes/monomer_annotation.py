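"""Per-residue disorder annotation and region segmentation of monomers.

Intrinsic structural disorder (ISD) is computed from the predicted monomer
structure, following the AlphaFold-derived disorder approach: the default
score is a centered moving average (window 25) of per-residue relative
solvent accessibility (RSA); an alternative windowed 1 - pLDDT/100 score is
also provided.  Residues with ISD > 0.5 in runs of >= 5 (with structured
gaps of < 3 residues absorbed) form intrinsically disordered regions (IDRs),
long if >= 30 residues.  Coil regions are the analogous runs of 3-state
coil.  Conditionally folded (CF) regions combine high ISD (> 0.5) with high
pLDDT (> 70): segments the monomer model folds confidently even though the
chain is intrinsically disordered, a signature of conformational-selection
binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .structure_io import MonomerModel

# Theoretical maximum solvent accessibility per residue type (Å²),
# Tien et al. 2013, used to normalize absolute SASA to RSA.
MAX_ACC = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Van der Waals radii (Å) for the Shrake-Rupley fallback.
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
_VDW_DEFAULT = 1.70
_PROBE = 1.4


@dataclass
class DisorderProfile:
    """Per-residue intrinsic structural disorder in [0, 1]."""

    isd: np.ndarray
    window: int
    variant: str

    def __post_init__(self) -> None:
        self.isd = np.asarray(self.isd, dtype=float)
        if np.any((self.isd < 0) | (self.isd > 1)):
            raise ValueError("ISD values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.isd)


@dataclass(frozen=True)
class Region:
    """1-based inclusive residue span of one kind."""

    start: int
    end: int
    kind: str = "ordered"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, residue_index: int) -> bool:
        return self.start <= residue_index <= self.end


@dataclass
class MonomerAnnotation:
    """All monomer tracks needed for binding-mode classification."""

    ss3: str
    isd: DisorderProfile
    plddt: np.ndarray
    idr_regions: list[Region] = field(default_factory=list)
    coil_regions: list[Region] = field(default_factory=list)
    cf_regions: list[Region] = field(default_factory=list)
    ordered_regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ss3)


def shrake_rupley_sasa(coords: np.ndarray, elements: list[str],
                       n_points: int = 960,
                       probe: float = _PROBE) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Fibonacci-lattice points on each atom's solvent-expanded sphere are
    tested for occlusion by every neighbouring sphere; the accessible
    fraction times the sphere area gives the atom's SASA.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([_VDW.get(e.upper(), _VDW_DEFAULT) for e in elements])
    radii = radii + probe
    # Fibonacci sphere
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * k / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * k
    unit = np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])
    sasa = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        free = np.ones(n_points, dtype=bool)
        d2 = np.sum((coords - coords[i]) ** 2, axis=1)
        near = np.where((d2 < (radii + radii[i]) ** 2) &
                        (np.arange(len(coords)) != i))[0]
        for j in near:
            free &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
        sasa[i] = 4 * np.pi * radii[i] ** 2 * free.mean()
    return sasa


def residue_sasa(monomer: MonomerModel, n_points: int = 960) -> np.ndarray:
    """Absolute per-residue SASA (Å²) from the built-in Shrake-Rupley."""
    coords, elements, owner = [], [], []
    for ri, res in enumerate(monomer.chain):
        for atom in res.heavy_atoms:
            coords.append(atom.position)
            elements.append(atom.element)
            owner.append(ri)
    atom_sasa = shrake_rupley_sasa(np.array(coords), elements, n_points)
    out = np.zeros(len(monomer))
    np.add.at(out, np.array(owner), atom_sasa)
    return out


def compute_rsa(monomer: MonomerModel,
                max_acc_scale: dict[str, float] | None = None) -> np.ndarray:
    """Relative solvent accessibility in [0, 1] per residue.

    Uses the monomer's absolute accessibility (typically from a DSSP
    record) when present, otherwise the built-in Shrake-Rupley; divides
    by the residue type's maximum accessibility and clips to [0, 1].
    """
    scale = MAX_ACC if max_acc_scale is None else max_acc_scale
    acc = monomer.accessibility
    if acc is None:
        acc = residue_sasa(monomer)
    rsa = np.empty(len(monomer))
    for i, res in enumerate(monomer.chain):
        if res.aa not in scale:
            raise KeyError(
                f"no max-accessibility entry for residue type {res.aa!r}")
        rsa[i] = acc[i] / scale[res.aa]
    return np.clip(rsa, 0.0, 1.0)


def _centered_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Moving average with shrinking windows at the termini."""
    n = len(values)
    if window == 1:
        return np.array(values, dtype=float)
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def compute_isd(plddt: np.ndarray, rsa: np.ndarray | None,
                window: int = 25,
                variant: str = "rsa_window") -> DisorderProfile:
    """Windowed intrinsic structural disorder score.

    ``rsa_window`` averages RSA over a centered window; ``plddt_window``
    averages 1 - pLDDT/100.  Windows shrink at the chain termini.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if variant == "rsa_window":
        if rsa is None:
            raise ValueError("rsa required for the rsa_window variant")
        base = np.asarray(rsa, dtype=float)
    elif variant == "plddt_window":
        base = 1.0 - np.asarray(plddt, dtype=float) / 100.0
    else:
        raise ValueError(f"unknown ISD variant {variant!r}")
    if plddt is not None and rsa is not None and len(plddt) != len(rsa):
        raise ValueError("plddt and rsa length mismatch")
    return DisorderProfile(isd=_centered_moving_average(base, window),
                           window=window, variant=variant)


_SS8_TO_SS3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def map_ss8_to_ss3(code8: str) -> str:
    """DSSP 8-state to 3-state: H/G/I -> H, E/B -> E, others -> C."""
    return _SS8_TO_SS3.get(code8, "C")


def ss3_from_ss8(ss8: str) -> str:
    return "".join(map_ss8_to_ss3(c) for c in ss8)


def segment_true_runs(mask, min_len: int = 5,
                      max_gap: int = 2, kind: str = "ordered") -> list[Region]:
    """Maximal true-runs with short false-gaps bridged, as 1-based regions.

    Gaps of at most ``max_gap`` consecutive false positions between true
    runs are absorbed; bridging happens before the ``min_len`` filter, so
    two short runs joined by a small gap can together pass the filter.
    """
    mask = np.asarray(mask, dtype=bool)
    runs = []
    start = None
    for i, val in enumerate(mask):
        if val and start is None:
            start = i
        elif not val and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [Region(s + 1, e + 1, kind) for s, e in merged
            if e - s + 1 >= min_len]


def _complement_regions(regions: list[Region], n: int) -> list[Region]:
    covered = np.zeros(n, dtype=bool)
    for r in regions:
        covered[r.start - 1:r.end] = True
    return segment_true_runs(~covered, min_len=1, max_gap=0, kind="ordered")


def annotate_monomer(monomer: MonomerModel | None, ss8: str,
                     params: PipelineConfig | None = None,
                     plddt: np.ndarray | None = None,
                     rsa: np.ndarray | None = None) -> MonomerAnnotation:
    """Segment one monomer into IDR / coil / CF / ordered regions.

    ``monomer`` supplies pLDDT and accessibility when given; ``plddt`` and
    ``rsa`` may be passed directly instead (e.g. from precomputed tracks).
    """
    params = params or PipelineConfig()
    if monomer is not None:
        plddt = monomer.plddt if plddt is None else np.asarray(plddt, float)
        rsa = compute_rsa(monomer) if rsa is None else np.asarray(rsa, float)
    if plddt is None:
        raise ValueError("need a monomer model or explicit plddt")
    plddt = np.asarray(plddt, dtype=float)
    if len(ss8) != len(plddt):
        raise ValueError(
            f"ss8 length {len(ss8)} != chain length {len(plddt)}")
    profile = compute_isd(plddt, rsa, window=params.isd_window,
                          variant=params.isd_variant)
    isd = profile.isd
    ss3 = ss3_from_ss8(ss8)
    min_len, gap = params.min_region, params.merge_gap

    idr = segment_true_runs(isd > params.isd_threshold, min_len, gap)
    idr = [Region(r.start, r.end,
                  "idr_long" if len(r) >= params.long_idr else "idr_short")
           for r in idr]
    coil = segment_true_runs([c == "C" for c in ss3], min_len, gap, "coil")
    cf = segment_true_runs((plddt > params.plddt_cf)
                           & (isd > params.isd_threshold),
                           min_len, gap, "cf")
    ordered = _complement_regions(idr, len(plddt))
    return MonomerAnnotation(ss3=ss3, isd=profile, plddt=plddt,
                             idr_regions=idr, coil_regions=coil,
                             cf_regions=cf, ordered_regions=ordered)
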