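"""Orchestrate the analysis stages as a reproducible pipeline.

A single declarative YAML config names the inputs and parameters; the
pipeline executes the stages in analysis order — haplotypes → distances →
diagnostic characters → networks → (genotypes) site filters → shared SNPs →
PCoA → diagnostic panel → hybrid metrics → classification → sex linkage →
maternal inference — skipping stages whose inputs are absent, and writes a
run manifest with the effective config, the seed, and a SHA-256 digest of
every input and output, so identical configs reproduce byte-identical
TSV/JSON outputs.

Config layout (all sections optional, but at least one of ``sequences`` /
``genotypes`` / ``simulate`` is required)::

    seed: 1
    config: {min_maf: 0.01, ...}          # Config overrides
    simulate:
      cross: {n_parent_a: 36, ...}        # generate inputs first
      sequences: {n_haplotypes: 12, ...}
    sequences:
      fasta: {COI: path/to/coi.fasta}
      metadata: path/to/specimens.tsv
      frames: {COI: 1}                    # genes to translation-check
      focal: hybrid                       # diagnostic-character focal taxon
    genotypes:
      path: path/to/genotypes.vcf        # or a dosage TSV
      counts: path/to/site_counts.tsv    # alternative: call from counts
      metadata: path/to/specimens.tsv
    hybrid:
      parent_a: taxonA
      parent_b: taxonB
      focal: hybrid
      maternal: taxonA                   # optional; inferred when absent
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import Config
from .hybrid import (
    build_fixed_panel,
    detect_sex_linked_loci,
    hybrid_report,
    infer_maternal_parent,
    pcoa_coordinates,
    shared_snp_counts,
)
from .io import (
    read_fasta,
    read_genotypes,
    read_metadata,
    read_site_counts,
    write_fasta,
    write_genotypes_tsv,
    write_metadata,
    write_vcf,
)
from .model import Sex, TaxonPartition
from .network import build_networks, network_composition
from .plots import plot_hybrid_metrics, plot_pcoa
from .seqdiv import (
    code_gaps,
    collapse_haplotypes,
    find_diagnostic_characters,
    group_distance_table,
    translation_check,
)
from .simulate import CrossDesign, simulate_cross_dataset, simulate_sequences
from .snpcall import call_matrix, filter_sites

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: effective config, seed, inputs and
    outputs with digests, package version and timestamps."""

    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)    # path -> digest
    outputs: dict[str, str] = field(default_factory=dict)   # path -> digest
    stages: list[str] = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def add_output(self, path: Path) -> None:
        self.outputs[path.name] = _sha256(path)

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_sequence_stage(
    aln, part: TaxonPartition, cfg: Config, out_dir: Path,
    focal: str | None = None, frame: int | None = None,
    manifest: RunManifest | None = None,
):
    """Haplotypes → distance table → diagnostic characters → gap coding →
    translation check → parsimony networks for one gene alignment."""
    out_dir.mkdir(parents=True, exist_ok=True)
    gene = aln.gene
    hap = collapse_haplotypes(aln, mode=cfg.haplotype_collapse)
    outputs = []

    members = pd.DataFrame(
        {"specimen_id": list(hap.membership),
         "haplotype": list(hap.membership.values())}
    )
    p = out_dir / f"{gene}_haplotypes.tsv"
    members.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    groups = [t for t in part.taxa if any(
        s in hap.membership for s in part.members(t))]
    table = group_distance_table(hap, part, groups)
    p = out_dir / f"{gene}_distances.tsv"
    table.to_tsv(p)
    outputs.append(p)

    if focal is not None and focal in part.taxa:
        chars = find_diagnostic_characters(
            aln, part, focal, mode=cfg.diagnostic_mode
        )
        p = out_dir / f"{gene}_diagnostic_characters.tsv"
        pd.DataFrame(
            [{"gene": gene, "position": c.position, "state": c.state,
              "focal_group": c.focal_group} for c in chars],
            columns=["gene", "position", "state", "focal_group"],
        ).to_csv(p, sep="\t", index=False)
        outputs.append(p)

    gaps = code_gaps(aln)
    if gaps.characters:
        p = out_dir / f"{gene}_gap_characters.tsv"
        gaps.to_frame().to_csv(p, sep="\t")
        outputs.append(p)

    if frame is not None:
        reports = translation_check(aln, frame=frame)
        p = out_dir / f"{gene}_translation_check.tsv"
        pd.DataFrame(
            [{"specimen_id": r.specimen_id, "ok": r.ok,
              "internal_stops": len(r.internal_stops),
              "ambiguous_residues": len(r.ambiguous_residues)}
             for r in reports]
        ).to_csv(p, sep="\t", index=False)
        outputs.append(p)

    net = build_networks(hap, confidence=cfg.network_confidence)
    p = out_dir / f"{gene}_network_edges.tsv"
    net.edge_list().to_csv(p, sep="\t", index=False)
    outputs.append(p)
    p = out_dir / f"{gene}_network_composition.tsv"
    network_composition(net, hap, part).to_csv(p, sep="\t", index=False)
    outputs.append(p)

    if manifest is not None:
        for p in outputs:
            manifest.add_output(p)
        manifest.stages.append(f"sequences:{gene}")
    return hap, net


def assign_mito_clusters(hap, net, part: TaxonPartition,
                         parent_a: str, parent_b: str) -> dict[str, str]:
    """Assign each specimen's mitochondrial haplotype to a parental
    cluster: the network component it falls in, provided that component
    contains specimens of exactly one parental taxon."""
    comp_taxa: dict[int, set[str]] = {}
    for i, comp in enumerate(net.components):
        taxa = set()
        for hid in comp:
            for s in hap.members_of(hid):
                t = part.assignments.get(s)
                if t in (parent_a, parent_b):
                    taxa.add(t)
        comp_taxa[i] = taxa
    assignments = {}
    for s, hid in hap.membership.items():
        try:
            ci = net.component_of(hid)
        except KeyError:
            continue  # haplotype dropped for ambiguity
        if len(comp_taxa[ci]) == 1:
            assignments[s] = next(iter(comp_taxa[ci]))
    return assignments


def run_genotype_stage(
    gm, records, part: TaxonPartition, cfg: Config, out_dir: Path,
    parent_a: str, parent_b: str, focal: str,
    maternal: str | None = None,
    mito_assignments: dict[str, str] | None = None,
    manifest: RunManifest | None = None,
) -> dict:
    """Site filters → shared SNPs → PCoA → panel → hybrid metrics +
    classification → sex linkage → maternal inference."""
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    results: dict = {}

    filtered, report = filter_sites(gm, cfg)
    p = out_dir / "site_filter_report.tsv"
    report.to_tsv(p)
    outputs.append(p)
    p = out_dir / "genotypes_filtered.tsv"
    write_genotypes_tsv(filtered, p)
    outputs.append(p)
    results["filter_summary"] = report.summary()

    others = [t for t in part.taxa if t != focal]
    shared = shared_snp_counts(filtered, part, focal, others, cfg)
    results["shared_snps"] = shared
    p = out_dir / "shared_snp_counts.json"
    with open(p, "w") as fh:
        json.dump(shared, fh, indent=2, sort_keys=True)
    outputs.append(p)

    rate = filtered.call_rate()
    pcoa_loci = [l for l in filtered.loci if rate[l] >= cfg.pcoa_min_call_rate]
    if len(pcoa_loci) >= 2 and filtered.n_specimens >= 3:
        coords, eig = pcoa_coordinates(filtered.subset(loci=pcoa_loci))
        p = out_dir / "pcoa_coordinates.tsv"
        coords.round(6).to_csv(p, sep="\t", index_label="specimen_id")
        outputs.append(p)
        plot_pcoa(coords, part.assignments, out_dir / "pcoa_scatter.png")
        results["pcoa_eigenvalues"] = [float(e) for e in eig]

    panel = build_fixed_panel(filtered, part, parent_a, parent_b, cfg)
    p = out_dir / "diagnostic_panel.tsv"
    panel.to_frame().to_csv(p, sep="\t", index=False)
    outputs.append(p)
    results["panel_size"] = panel.n_loci

    focal_specimens = [
        s for s in part.members(focal) if s in filtered.calls.index
    ]

    if mito_assignments:
        inference = infer_maternal_parent(
            {s: t for s, t in mito_assignments.items()
             if s in focal_specimens},
            panel, focal_specimens,
        )
        results["maternal_parent"] = inference.maternal_parent
        results["cross_direction"] = inference.direction
        if maternal is None and inference.maternal_parent != "bidirectional":
            maternal = inference.maternal_parent

    # sex-linkage detection first: hemizygous male genotypes at X-linked
    # panel loci would otherwise bias the autosomal hybrid metrics
    metrics_panel = panel
    sex_of = {r.specimen_id: r.sex for r in records}
    sexed = [s for s in focal_specimens
             if sex_of.get(s) in (Sex.MALE, Sex.FEMALE)]
    if maternal is not None and sexed and panel.n_loci:
        linkage = detect_sex_linked_loci(
            filtered, panel, sex_of, sexed, maternal, cfg
        )
        p = out_dir / "sex_linkage.tsv"
        linkage.table.to_csv(p, sep="\t")
        outputs.append(p)
        results["sex_linkage_summary"] = linkage.summary()
        autosomal = [
            l for l in panel.loci
            if l not in set(linkage.loci_with_status("sex_linked"))
        ]
        metrics_panel = panel.subset(autosomal)

    report_df = hybrid_report(filtered, metrics_panel, focal_specimens, cfg)
    p = out_dir / "hybrid_metrics.tsv"
    report_df.round(6).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    plot_hybrid_metrics(report_df, out_dir / "hybrid_metrics.png")
    results["class_counts"] = (
        report_df["hybrid_class"].value_counts().to_dict()
    )

    p = out_dir / "hybrid_summary.json"
    with open(p, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
    outputs.append(p)

    if manifest is not None:
        for q in outputs:
            manifest.add_output(q)
        manifest.stages.append("genotypes")
    return results


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def run_full_analysis(config_path: str | Path, out_dir: str | Path,
                      seed: int | None = None) -> RunManifest:
    """Execute the configured stages in analysis order and write a
    manifest.  Input validation happens before any computation."""
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    with open(config_path) as fh:
        spec = yaml.safe_load(fh) or {}
    cfg = Config.from_dict(spec.get("config", {}))
    if seed is None:
        seed = int(spec.get("seed", cfg.rng_seed))
    cfg.rng_seed = seed

    seq_spec = spec.get("sequences")
    geno_spec = spec.get("genotypes")
    sim_spec = spec.get("simulate")
    _require(
        seq_spec is not None or geno_spec is not None or sim_spec is not None,
        "config must name at least one of: sequences, genotypes, simulate",
    )
    # fail fast on missing input files, before any computation
    for section in (seq_spec, geno_spec):
        if not section:
            continue
        for key in ("metadata", "path", "counts"):
            value = section.get(key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"missing input file: {value}")
        for path in (section.get("fasta") or {}).values():
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input file: {path}")

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={"seed": seed, "config": cfg.to_dict(), **{
            k: v for k, v in spec.items() if k not in ("config", "seed")
        }},
        seed=seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for section in (seq_spec, geno_spec):
        if not section:
            continue
        for key in ("metadata", "path", "counts"):
            if section.get(key):
                manifest.inputs[str(section[key])] = _sha256(Path(section[key]))
        for path in (section.get("fasta") or {}).values():
            manifest.inputs[str(path)] = _sha256(Path(path))

    mito_assignments = None
    hybrid_spec = dict(spec.get("hybrid") or {})

    # --- optional simulation stage generates the inputs ---
    if sim_spec is not None:
        sim_dir = out_dir / "inputs"
        sim_dir.mkdir(exist_ok=True)
        if "cross" in sim_spec:
            params = dict(sim_spec["cross"])
            params.setdefault("seed", seed)
            result = simulate_cross_dataset(CrossDesign(**params))
            write_metadata(result.records, sim_dir / "specimens.tsv")
            write_vcf(result.genotypes, sim_dir / "genotypes.vcf")
            write_fasta(result.mito, sim_dir / "mito.fasta")
            result.specimen_truth.to_csv(
                sim_dir / "specimen_truth.tsv", sep="\t", index=False
            )
            result.locus_truth.to_csv(
                sim_dir / "locus_truth.tsv", sep="\t", index=False
            )
            for name in ("specimens.tsv", "genotypes.vcf", "mito.fasta",
                         "specimen_truth.tsv", "locus_truth.tsv"):
                manifest.add_output(sim_dir / name)
            manifest.stages.append("simulate:cross")
            geno_spec = geno_spec or {}
            geno_spec.setdefault("path", str(sim_dir / "genotypes.vcf"))
            geno_spec.setdefault("metadata", str(sim_dir / "specimens.tsv"))
            seq_spec = seq_spec or {}
            seq_spec.setdefault("fasta", {"COI": str(sim_dir / "mito.fasta")})
            seq_spec.setdefault("metadata", str(sim_dir / "specimens.tsv"))
            hybrid_spec.setdefault("parent_a", result.design.taxon_a)
            hybrid_spec.setdefault("parent_b", result.design.taxon_b)
            hybrid_spec.setdefault("focal", result.design.hybrid_label)
        if "sequences" in sim_spec:
            params = dict(sim_spec["sequences"])
            params.setdefault("seed", seed)
            aln, truth = simulate_sequences(**params)
            write_fasta(aln, sim_dir / "sequences.fasta")
            truth.to_csv(sim_dir / "sequence_truth.tsv", sep="\t", index=False)
            manifest.add_output(sim_dir / "sequences.fasta")
            manifest.add_output(sim_dir / "sequence_truth.tsv")
            manifest.stages.append("simulate:sequences")

    # --- sequence stage ---
    if seq_spec:
        records = read_metadata(seq_spec["metadata"])
        part = TaxonPartition.from_records(records)
        frames = seq_spec.get("frames") or {}
        focal = seq_spec.get("focal", hybrid_spec.get("focal"))
        for gene, path in (seq_spec.get("fasta") or {}).items():
            aln = read_fasta(path, gene=gene)
            hap, net = run_sequence_stage(
                aln, part, cfg, out_dir / "sequences",
                focal=focal, frame=frames.get(gene), manifest=manifest,
            )
            if (mito_assignments is None
                    and hybrid_spec.get("parent_a")
                    and hybrid_spec.get("parent_b")):
                mito_assignments = assign_mito_clusters(
                    hap, net, part,
                    hybrid_spec["parent_a"], hybrid_spec["parent_b"],
                )
    else:
        logger.info("no sequence inputs configured; sequence stages skipped")

    # --- genotype stage ---
    if geno_spec:
        records = read_metadata(geno_spec["metadata"])
        part = TaxonPartition.from_records(records)
        if geno_spec.get("counts"):
            table = read_site_counts(geno_spec["counts"])
            gm = call_matrix(table, cfg)
        else:
            gm = read_genotypes(
                geno_spec["path"], geno_spec.get("format", "auto")
            )
        _require("parent_a" in hybrid_spec and "parent_b" in hybrid_spec,
                 "genotype stage requires hybrid.parent_a and hybrid.parent_b")
        _require("focal" in hybrid_spec,
                 "genotype stage requires hybrid.focal")
        run_genotype_stage(
            gm, records, part, cfg, out_dir / "genotypes",
            parent_a=hybrid_spec["parent_a"],
            parent_b=hybrid_spec["parent_b"],
            focal=hybrid_spec["focal"],
            maternal=hybrid_spec.get("maternal"),
            mito_assignments=mito_assignments,
            manifest=manifest,
        )
    else:
        logger.info("no genotype inputs configured; genotype stages skipped")

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out_dir / "manifest.json")
    return manifest
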