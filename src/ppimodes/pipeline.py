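"""Per-pair orchestration and batch aggregation.

``run_pair`` executes the full per-dimer analysis: heavy-atom contact
detection, PAE filtering, interface-region merging, confidence scoring,
and binding-mode classification against the two monomer annotations.
``run_batch`` maps it over a manifest of input files, writes the
pair-summary CSV, counts binding modes over high-confidence pairs, and
reports the network structure.  ``replicate_from_summary`` skips the
structural stages and rebuilds the network statistics from an existing
pair-summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import structure_io as sio
from .binding_modes import (PPI_FLAGS, PPIModeSummary, RegionModeAnnotation,
                            aggregate_ppi_modes, classify_interface_region)
from .config import PipelineConfig
from .confidence_scoring import ConfidenceSummary, assign_tier, score_complex
from .interface_detection import (build_interface_regions,
                                  filter_contacts_by_pae, find_contacts)
from .monomer_annotation import (MonomerAnnotation, annotate_monomer,
                                 ss3_from_ss8)
from .structure_io import ComplexModel, MonomerModel

logger = logging.getLogger("ppimodes")

#: Manifest columns required by :func:`run_batch`.
MANIFEST_COLUMNS = ("pair_id", "protein_a", "protein_b", "complex", "pae",
                    "monomer_a", "monomer_b", "dssp_monomer_a",
                    "dssp_monomer_b", "dssp_complex")


@dataclass
class PairRecord:
    """Everything computed for one protein pair."""

    pair_id: str
    protein_a: str
    protein_b: str
    confidence: ConfidenceSummary
    regions_a: list[RegionModeAnnotation]
    regions_b: list[RegionModeAnnotation]
    modes: PPIModeSummary
    ilis: float | None = None

    def interface_spans(self) -> dict[str, list[tuple[int, int]]]:
        spans: dict[str, list[tuple[int, int]]] = {}
        for ann in self.regions_a + self.regions_b:
            spans.setdefault(ann.region.chain, []).append(
                (ann.region.span.start, ann.region.span.end))
        return spans

    def to_summary_row(self) -> dict:
        row = {
            "pair_id": self.pair_id,
            "protein_a": self.protein_a,
            "protein_b": self.protein_b,
            "iptm": self.confidence.iptm,
            "min_interchain_pae": self.confidence.min_interchain_pae,
            "pdockq": self.confidence.pdockq,
            "ilis": "" if self.ilis is None else self.ilis,
            "tier": self.confidence.tier,
            "interface_residues":
                sio.format_interface_spans(self.interface_spans()),
        }
        region_flags = set()
        for ann in self.regions_a + self.regions_b:
            region_flags |= ann.flags
        for flag in sio.MODE_FLAGS:
            source = self.modes.flags if flag in PPI_FLAGS else region_flags
            row[f"mode_{flag}"] = int(flag in source)
        return row


def run_pair(complex_model: ComplexModel,
             annotation_a: MonomerAnnotation,
             annotation_b: MonomerAnnotation,
             complex_ss8_a: str, complex_ss8_b: str,
             config: PipelineConfig | None = None,
             pair_id: str = "pair", protein_a: str = "A",
             protein_b: str = "B", iptm: float = 0.0,
             ilis: float | None = None) -> PairRecord:
    """Full per-pair analysis; binding modes are computed for every tier."""
    config = config or PipelineConfig()
    contacts = find_contacts(complex_model, config.contact_cutoff)
    contacts = filter_contacts_by_pae(contacts, complex_model,
                                      config.pae_exclude, config.pae_combine)
    regions = {
        cid: build_interface_regions(contacts, cid, config.merge_gap)
        for cid in (complex_model.chain_id_a, complex_model.chain_id_b)}
    confidence = score_complex(complex_model, iptm=iptm, thresholds=config)
    cplx_ss3 = {complex_model.chain_id_a: ss3_from_ss8(complex_ss8_a),
                complex_model.chain_id_b: ss3_from_ss8(complex_ss8_b)}
    annotations = {complex_model.chain_id_a: annotation_a,
                   complex_model.chain_id_b: annotation_b}
    classified = {
        cid: [classify_interface_region(r, annotations[cid], cplx_ss3[cid],
                                        config)
              for r in regs]
        for cid, regs in regions.items()}
    all_regions = [ann for regs in classified.values() for ann in regs]
    modes = aggregate_ppi_modes(all_regions, pair_id=pair_id)
    return PairRecord(pair_id=pair_id, protein_a=protein_a,
                      protein_b=protein_b, confidence=confidence,
                      regions_a=classified[complex_model.chain_id_a],
                      regions_b=classified[complex_model.chain_id_b],
                      modes=modes, ilis=ilis)


def load_monomer_annotation(structure_path: str | Path,
                            dssp_path: str | Path,
                            config: PipelineConfig | None = None,
                            ) -> MonomerAnnotation:
    """Read a monomer structure + DSSP record and annotate it."""
    config = config or PipelineConfig()
    monomer = sio.read_structure(structure_path)
    if not isinstance(monomer, MonomerModel):
        raise sio.StructureIOError(f"{structure_path} is not a monomer")
    records = sio.read_ss_record(dssp_path)
    chain_id = monomer.chain_id
    ss8 = sio.ss8_string(records, chain_id)
    acc = sio.acc_array(records, chain_id)
    if len(ss8) != len(monomer):
        raise sio.StructureIOError(
            f"DSSP record has {len(ss8)} residues but structure has "
            f"{len(monomer)}")
    monomer.accessibility = acc
    return annotate_monomer(monomer, ss8, config)


def run_pair_from_files(row: dict, config: PipelineConfig) -> PairRecord:
    """Run one manifest row (paths to complex, PAE, monomers, DSSP files)."""
    complex_model = sio.read_structure(row["complex"])
    if not isinstance(complex_model, ComplexModel):
        raise sio.StructureIOError(f"{row['complex']} is not a dimer")
    complex_model.pae = sio.read_pae(row["pae"])
    ann_a = load_monomer_annotation(row["monomer_a"],
                                    row["dssp_monomer_a"], config)
    ann_b = load_monomer_annotation(row["monomer_b"],
                                    row["dssp_monomer_b"], config)
    cplx_records = sio.read_ss_record(row["dssp_complex"])
    ss8_a = sio.ss8_string(cplx_records, complex_model.chain_id_a)
    ss8_b = sio.ss8_string(cplx_records, complex_model.chain_id_b)
    iptm = float(row.get("iptm", 0.0) or 0.0)
    ilis = row.get("ilis")
    ilis = None if ilis in (None, "") or pd.isna(ilis) else float(ilis)
    return run_pair(complex_model, ann_a, ann_b, ss8_a, ss8_b, config,
                    pair_id=str(row["pair_id"]),
                    protein_a=str(row["protein_a"]),
                    protein_b=str(row["protein_b"]),
                    iptm=iptm, ilis=ilis)


@dataclass
class BatchResult:
    summary: pd.DataFrame
    mode_counts: dict[str, int]
    network_report: dict
    failures: list[tuple[str, str]] = field(default_factory=list)


def count_modes(summary: pd.DataFrame, tier: str | None = "high") -> dict:
    """Count PPIs per mode flag, by default over the high tier only.

    Passing ``tier=None`` widens the denominator to all pairs.
    """
    df = summary if tier is None else summary[summary["tier"] == tier]
    counts = {"n_ppis": int(len(df))}
    for flag in sio.MODE_FLAGS:
        col = f"mode_{flag}"
        counts[flag] = int(df[col].astype(float).sum()) if col in df else 0
    return counts


def network_report(summary: pd.DataFrame,
                   config: PipelineConfig | None = None,
                   include_mcl: bool = True) -> dict:
    """Tier counts plus component / degree / cluster statistics.

    The graph is built from pairs at the high tier (pDockQ >= the
    configured high threshold).
    """
    from . import network_analysis as net

    config = config or PipelineConfig()
    df = summary.copy()
    if "tier" not in df.columns or df["tier"].isna().any():
        df["tier"] = [
            assign_tier(ConfidenceSummary(
                pdockq=float(r.pdockq),
                iptm=_norm_iptm(getattr(r, "iptm", 0.0)),
                min_interchain_pae=float(getattr(r, "min_interchain_pae",
                                                 np.inf)),
                n_if_contacts=0, mean_if_plddt=0.0), config)
            for r in df.itertuples(index=False)]
    tier_counts = df["tier"].value_counts().to_dict()
    graph = net.build_graph(df, pdockq_min=config.pdockq_high)
    report = {
        "config": config.to_dict(),
        "n_pairs": int(len(df)),
        "tier_counts": {t: int(c) for t, c in tier_counts.items()},
        "n_edges": graph.number_of_edges(),
        "n_nodes": graph.number_of_nodes(),
    }
    if graph.number_of_nodes():
        comps = net.connected_components(graph)
        mean_degree, hist = net.degree_stats(graph)
        report.update({
            "component_edge_counts": [c.n_edges for c in comps],
            "n_components": len(comps),
            "n_singletons": net.n_singletons(comps),
            "largest_component_edges": comps[0].n_edges,
            "largest_component_nodes": comps[0].n_nodes,
            "mean_degree": mean_degree,
            "degree_histogram": {int(k): int(v) for k, v in hist.items()},
        })
        if include_mcl:
            mcl = net.mcl_cluster(graph, inflation=config.mcl_inflation)
            report["mcl"] = {"n_clusters": len(mcl.clusters),
                             "converged": mcl.converged,
                             "iterations": mcl.iterations}
    else:
        report.update({"component_edge_counts": [], "n_components": 0,
                       "n_singletons": 0, "mean_degree": 0.0})
    return report


def _norm_iptm(value) -> float:
    """ipTM on [0, 1]; percent-style inputs (e.g. 85) are rescaled."""
    try:
        v = float(value)
    except (TypeError, ValueError):
        return 0.0
    if np.isnan(v):
        return 0.0
    return v / 100.0 if v > 1.0 else v


def run_batch(manifest: pd.DataFrame | str | Path,
              config: PipelineConfig | None = None,
              summary_path: str | Path | None = None,
              include_mcl: bool = True) -> BatchResult:
    """Run every manifest row; failures are logged and skipped."""
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise ValueError("empty manifest")
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    records, failures = [], []
    for row in manifest.to_dict("records"):
        try:
            rec = run_pair_from_files(row, config)
        except Exception as exc:  # noqa: BLE001 - skip-and-log per pair
            logger.warning("pair %s failed: %s", row.get("pair_id"), exc)
            failures.append((str(row.get("pair_id")), str(exc)))
            continue
        logger.info("pair %s tier=%s flags=%s", rec.pair_id,
                    rec.confidence.tier, sorted(rec.modes.flags))
        records.append(rec)
    summary = pd.DataFrame([r.to_summary_row() for r in records])
    summary = summary.sort_values("pair_id").reset_index(drop=True) \
        if len(summary) else summary
    if summary_path is not None:
        sio.write_pair_summary(summary, summary_path)
    modes = count_modes(summary) if len(summary) else {"n_ppis": 0}
    report = network_report(summary, config, include_mcl) if len(summary) \
        else {"n_pairs": 0}
    report["n_failures"] = len(failures)
    return BatchResult(summary=summary, mode_counts=modes,
                       network_report=report, failures=failures)


def replicate_from_summary(summary: pd.DataFrame | str | Path,
                           config: PipelineConfig | None = None,
                           include_mcl: bool = False) -> dict:
    """Network statistics straight from a pair-summary table.

    This is the replication entry point for externally produced
    prediction tables: no structures are read, tiers are derived from
    the score columns when absent, and component / degree / singleton
    statistics are reported for the high-confidence graph.
    """
    config = config or PipelineConfig()
    if not isinstance(summary, pd.DataFrame):
        summary = sio.read_pair_summary(summary)
    if summary.empty:
        raise ValueError("empty summary table")
    return network_report(summary, config, include_mcl=include_mcl)


def annotation_track_table(annotation: MonomerAnnotation) -> pd.DataFrame:
    """Per-residue export of the monomer annotation tracks."""
    n = len(annotation)
    flags = {kind: np.zeros(n, dtype=int)
             for kind in ("idr", "idr_long", "coil", "cf", "ordered")}
    for r in annotation.idr_regions:
        flags["idr"][r.start - 1:r.end] = 1
        if r.kind == "idr_long":
            flags["idr_long"][r.start - 1:r.end] = 1
    for r in annotation.coil_regions:
        flags["coil"][r.start - 1:r.end] = 1
    for r in annotation.cf_regions:
        flags["cf"][r.start - 1:r.end] = 1
    for r in annotation.ordered_regions:
        flags["ordered"][r.start - 1:r.end] = 1
    return pd.DataFrame({
        "residue": np.arange(1, n + 1),
        "plddt": annotation.plddt,
        "isd": annotation.isd.isd,
        "ss3": list(annotation.ss3),
        **{f"in_{k}": v for k, v in flags.items()},
    })
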