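"""End-to-end orchestration: simulate -> demux -> annotate -> quantify ->
differential expression -> enrichment -> qPCR cross-validation.

Each stage writes its artifacts (TSV/FASTA/FASTQ) before the next starts,
so any stage can also be run standalone on externally supplied files.  The
summary report is assembled from stage outputs only; no number in it is
recomputed independently of the artifact it summarizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotate import AnnotationSummary, annotate_library, apply_fragment_exclusion
from .demux import BarcodeTable, demultiplex
from .diffexp import (
    call_differential,
    cluster_matrix,
    hierarchical_cluster,
    results_to_frame,
    to_newick,
)
from .enrichment import enrich, results_to_frame as enrichment_frame, select_target_genes
from .io import write_fastq, write_insert_fastas, write_tally
from .qpcr import analyze_ct_table, correlate_platforms
from .quantify import CountTable, abundant_set, exclusive_features, filter_reliable, normalize_cpm
from .sim import (
    SimConfig,
    simulate_qpcr,
    simulate_reads,
    simulate_references,
    simulate_target_map,
    simulate_term_map,
)

__all__ = ["PipelineConfig", "SummaryReport", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline.

    Serializes losslessly to a flat ``key=value`` text file with
    JSON-encoded values (stage-prefixed keys for the stage parameters,
    ``sim.``-prefixed keys for the generator).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    demux_min_len: int = 15
    demux_max_len: int = 35
    min_count: int = 10
    abundant_threshold: int = 20
    abundant_strict: bool = True
    fc_threshold: float = 2.0
    p_threshold: float = 0.001
    pseudocount: float = 0.5
    enrich_min_hits: int = 2
    enrich_alpha: float = 0.05
    enrich_correction: str = "bh"
    target_map_path: Optional[str] = None
    term_map_path: Optional[str] = None
    qpcr_n_mirnas: int = 12
    qpcr_noise_sd: float = 0.1
    qpcr_efficiency: float = 2.0
    top_n: int = 20

    def to_flat(self) -> dict[str, str]:
        flat: dict[str, str] = {}
        for f in dataclasses.fields(SimConfig):
            value = getattr(self.sim, f.name)
            if isinstance(value, dict):
                value = {str(k): v for k, v in value.items()}
            flat[f"sim.{f.name}"] = json.dumps(value)
        for f in dataclasses.fields(self):
            if f.name == "sim":
                continue
            flat[f.name] = json.dumps(getattr(self, f.name))
        return flat

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_flat().items():
                fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        flat: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                flat[key] = value
        sim_kwargs = {}
        kwargs = {}
        int_keyed = {"length_distribution"}
        for key, raw in flat.items():
            value = json.loads(raw)
            if key.startswith("sim."):
                name = key[4:]
                if name in int_keyed and isinstance(value, dict):
                    value = {int(k): v for k, v in value.items()}
                sim_kwargs[name] = value
            else:
                kwargs[key] = value
        return cls(sim=SimConfig(**sim_kwargs), **kwargs)


@dataclass
class SummaryReport:
    """Run summary assembled from the stage artifacts."""

    config_hash: str
    seed: int
    demux_tallies: dict[str, dict[str, int]] = field(default_factory=dict)
    length_histograms: dict[str, dict[int, int]] = field(default_factory=dict)
    category_percentages: dict[str, dict[str, float]] = field(default_factory=dict)
    detected: dict[str, dict[str, int]] = field(default_factory=dict)
    abundant_sizes: dict[str, int] = field(default_factory=dict)
    de_counts: dict[str, int] = field(default_factory=dict)
    exclusive_sizes: dict[str, int] = field(default_factory=dict)
    top_expressed: dict[str, pd.DataFrame] = field(default_factory=dict)
    de_table: Optional[pd.DataFrame] = None
    enrichment_table: Optional[pd.DataFrame] = None
    platform_correlation: Optional[float] = None
    platform_n: int = 0

    def de_feature_names(self) -> list[str]:
        if self.de_table is None:
            return []
        return list(self.de_table.loc[self.de_table["call"] != "ns", "feature"])

    def serum_only_features(self) -> frozenset[str]:
        if self.de_table is None:
            return frozenset()
        return frozenset(
            self.de_table.loc[self.de_table["exclusive"] == "serum_only", "feature"]
        )


def run_pipeline(config: PipelineConfig, out_dir) -> SummaryReport:
    """Run every stage in dependency order on synthetic data.

    Deterministic given the configuration (including the seed): running the
    same config twice produces byte-identical artifacts and reports.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")
    config_hash = hashlib.sha256(
        "\n".join(f"{k}={v}" for k, v in sorted(config.to_flat().items())).encode()
    ).hexdigest()[:16]
    report = SummaryReport(config_hash=config_hash, seed=config.sim.seed)

    # --- simulate ---------------------------------------------------------
    refs = simulate_references(config.sim)
    refs.to_fasta(out / "references.fasta")
    reads, truth = simulate_reads(config.sim, refs)
    write_fastq(reads, out / "reads.fastq")
    truth.reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)

    # --- demux ------------------------------------------------------------
    table = BarcodeTable(dict(config.sim.barcodes))
    table.to_tsv(out / "barcodes.tsv")
    adaptor = config.sim.adaptor if config.sim.with_adaptor else None
    results, tally = demultiplex(
        reads,
        table,
        adaptor=adaptor,
        min_len=config.demux_min_len,
        max_len=config.demux_max_len,
    )
    write_tally(tally, out / "demux_tally.tsv")
    write_insert_fastas(results, out)

    # --- annotate + quantify per library ----------------------------------
    counts: dict[str, CountTable] = {}
    for lib in config.sim.libraries:
        inserts = [r.insert for r in results if r.status == "kept" and r.assignment == lib]
        if not inserts:
            raise RuntimeError(f"annotate: no kept inserts for library {lib!r}")
        summary = annotate_library(inserts, refs, library_id=lib)
        _write_annotation_summary(summary, out / f"annotation.{lib}.tsv")
        feature_counts = apply_fragment_exclusion(summary.feature_counts, refs)
        counts[lib] = CountTable(lib, dict(feature_counts))
        counts[lib].to_tsv(out / f"counts.{lib}.tsv")
        report.demux_tallies[lib] = {
            "kept": len(inserts),
        }
        report.length_histograms[lib] = summary.length_counts
        report.category_percentages[lib] = summary.percentages
        mirna_n, star_n = summary.mirna_star_split()
        report.detected[lib] = {
            "features": len(feature_counts),
            "mirna": mirna_n,
            "mirna_star": star_n,
        }
    report.demux_tallies["all"] = tally

    serum, plasma = counts["serum"], counts["plasma"]
    for lib, tab in counts.items():
        reliable = filter_reliable(tab, config.min_count)
        normalize_cpm(reliable).to_tsv(out / f"cpm.{lib}.tsv") if reliable.size else None
        report.abundant_sizes[lib] = len(
            abundant_set(tab, config.abundant_threshold, config.abundant_strict)
        )
        top = (
            pd.DataFrame(
                {"feature": list(tab.counts), "count": list(tab.counts.values())}
            )
            .sort_values(["count", "feature"], ascending=[False, True])
            .head(config.top_n)
            .reset_index(drop=True)
        )
        report.top_expressed[lib] = top
        top.to_csv(out / f"top{config.top_n}.{lib}.tsv", sep="\t", index=False)
    only_s, only_p, shared = exclusive_features(
        set(filter_reliable(serum, config.min_count).counts),
        set(filter_reliable(plasma, config.min_count).counts),
    )
    report.exclusive_sizes = {
        "serum_only": len(only_s),
        "plasma_only": len(only_p),
        "shared": len(shared),
    }

    # --- differential expression ------------------------------------------
    de_results = call_differential(
        serum,
        plasma,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
        pseudocount=config.pseudocount,
        min_count=config.min_count,
    )
    de_frame = results_to_frame(de_results)
    de_frame.to_csv(out / "de_results.tsv", sep="\t", index=False)
    report.de_table = de_frame
    report.de_counts = {
        "up": int((de_frame["call"] == "up").sum()),
        "down": int((de_frame["call"] == "down").sum()),
        "ns": int((de_frame["call"] == "ns").sum()),
    }
    matrix = cluster_matrix(de_results, called_only=True)
    if matrix.shape[0] >= 2:
        clust = hierarchical_cluster(matrix)
        (out / "dendrogram.newick").write_text(to_newick(clust) + "\n")
        matrix.loc[clust.leaf_order].to_csv(out / "cluster_matrix.tsv", sep="\t")

    # --- enrichment -------------------------------------------------------
    de_mirnas = [r.feature for r in de_results if r.call != "ns"]
    if config.target_map_path:
        from .enrichment import read_target_map

        targets = read_target_map(config.target_map_path)
    else:
        targets = simulate_target_map(sorted(set(de_mirnas)), seed=config.sim.seed)
    query = select_target_genes(targets, de_mirnas, config.enrich_min_hits)
    if config.term_map_path:
        from .enrichment import TermMap

        terms = TermMap.from_gmt(config.term_map_path)
    else:
        universe = sorted(set().union(*targets.values())) if targets else []
        terms = (
            simulate_term_map(universe, sorted(query), seed=config.sim.seed)
            if universe
            else None
        )
    if terms is not None and len(query) > 0:
        enr = enrich(
            query,
            terms,
            min_hits=config.enrich_min_hits,
            alpha=config.enrich_alpha,
            correction=config.enrich_correction,
        )
        report.enrichment_table = enrichment_frame(enr)
        report.enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- qPCR cross-validation --------------------------------------------
    called = [r for r in de_results if r.call != "ns"]
    called.sort(key=lambda r: r.p_value)
    selected = called[: config.qpcr_n_mirnas]
    if len(selected) >= 3:
        true_fc = {
            r.feature: truth.fold_changes.get(r.feature, 2.0 ** r.log2fc)
            for r in selected
        }
        ct = simulate_qpcr(true_fc, config.sim, noise_sd=config.qpcr_noise_sd)
        ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        qpcr_results = analyze_ct_table(ct, efficiency=config.qpcr_efficiency)
        seq_fc = {r.feature: r.log2fc for r in selected}
        qpcr_fc = {r.mirna: r.log2_fold_change for r in qpcr_results}
        corr = correlate_platforms(seq_fc, qpcr_fc)
        if corr.defined:
            report.platform_correlation = corr.r
        report.platform_n = corr.n
        pd.DataFrame(
            {
                "miRNA": sorted(set(seq_fc) & set(qpcr_fc)),
            }
        ).assign(
            seq_log2fc=lambda d: d["miRNA"].map(seq_fc),
            qpcr_log2fc=lambda d: d["miRNA"].map(qpcr_fc),
        ).to_csv(out / "platform_comparison.tsv", sep="\t", index=False)

    render_report(report, out / "report.txt")
    return report


def _write_annotation_summary(summary: AnnotationSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("# category composition\ncategory\tcount\tpercent\n")
        pct = summary.percentages
        for cat in sorted(summary.category_counts):
            fh.write(f"{cat}\t{summary.category_counts[cat]}\t{pct[cat]:.4f}\n")
        fh.write(f"unannotated\t{summary.unannotated}\t{pct.get('unannotated', 0.0):.4f}\n")
        fh.write("# length histogram\nlength\tcount\n")
        for length in sorted(summary.length_counts):
            fh.write(f"{length}\t{summary.length_counts[length]}\n")
        fh.write("# per-feature counts\nfeature\tcount\n")
        for feat in sorted(summary.feature_counts):
            fh.write(f"{feat}\t{summary.feature_counts[feat]}\n")


def render_report(report: SummaryReport, path) -> str:
    """Render the summary as deterministic plain text; returns the text."""
    lines = [
        f"circmir {__version__} run summary",
        f"config_hash: {report.config_hash}",
        f"seed: {report.seed}",
        "",
        "[demultiplexing]",
    ]
    for lib, tally in sorted(report.demux_tallies.items()):
        entries = ", ".join(f"{k}={v}" for k, v in sorted(tally.items()))
        lines.append(f"  {lib}: {entries}")
    lines.append("")
    lines.append("[composition]")
    for lib, pct in sorted(report.category_percentages.items()):
        entries = ", ".join(f"{k}={v:.2f}%" for k, v in sorted(pct.items()))
        lines.append(f"  {lib}: {entries}")
    lines.append("")
    lines.append("[detection]")
    for lib, det in sorted(report.detected.items()):
        lines.append(
            f"  {lib}: {det['features']} features "
            f"({det['mirna']} miRNA, {det['mirna_star']} miRNA*)"
        )
    lines.append("")
    lines.append("[abundance and exclusivity]")
    for lib, n in sorted(report.abundant_sizes.items()):
        lines.append(f"  abundant ({lib}): {n}")
    for key, n in sorted(report.exclusive_sizes.items()):
        lines.append(f"  {key}: {n}")
    lines.append("")
    lines.append("[differential expression]")
    for key in ("up", "down", "ns"):
        lines.append(f"  {key}: {report.de_counts.get(key, 0)}")
    if report.platform_correlation is not None:
        lines.append("")
        lines.append("[platform cross-validation]")
        lines.append(
            f"  Pearson r (sequencing vs qPCR log2FC): "
            f"{report.platform_correlation:.3f} over {report.platform_n} miRNAs"
        )
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
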