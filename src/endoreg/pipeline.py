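"""End-to-end orchestration with a YAML config and a reproducible report.

A run executes the analysis stages in dependency order — synthesis (or
loading) of the annotated genome, physical-property profiling, null
models, motif scanning, intergenic classification, neighbourhood
conservation, and category statistics — writing versioned TSV/JSON
outputs plus a manifest (seed, parameters, SHA-256 of every output) so
reruns with the same config and seed are byte-identical.

External sigma-70 promoter predictions are ingested as a table rather
than computed (the predictors are external binaries with unpublished
scoring); the 5' UTR length summary derives from whatever table is
supplied.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    association_stats,
    conservation_graphs,
    dna_physics,
    genome_model,
    intergenic_analysis,
    motif_scan,
    null_models,
    synthetic_data,
)

__all__ = ["PipelineConfig", "run_pipeline", "ingest_promoters"]

_ALL_STAGES = ("synth", "physics", "nulls", "scan", "intergenic", "conserve", "stats")


@dataclass
class PipelineConfig:
    seed: int                              # mandatory
    outdir: str = "endoreg_run"
    # inputs: either real files or a synthetic preset
    fasta: str = None
    annotation: str = None
    tu_table: str = None
    networks: str = None                   # 3-column TSV edge list
    orthology: str = None
    promoters: str = None                  # external promoter predictions
    preset: str = "buchnera-like"
    n_genes: int = 550
    stages: tuple = _ALL_STAGES
    # analysis parameters
    genome_window_bp: int = 300
    promoter_smooth_bp: int = 20
    upstream_scan_bp: int = 500
    promoter_window_bp: int = 150
    sidd: dict = field(default_factory=dict)
    null_kind: str = "global"
    null_replicates: int = 1
    resampling: dict = field(
        default_factory=lambda: {"n_sims": 1000, "cap": 38, "min_shared": 2, "span": 5}
    )
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("pipeline config must set a seed")
        cfg = cls(**raw)
        for key in ("fasta", "annotation", "tu_table", "networks", "orthology",
                    "promoters"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {key} path does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def ingest_promoters(path):
    """Read an external promoter-prediction table and summarise 5' UTRs.

    Expects TSV columns gene_id, predicted_start_offset (negative =
    upstream of the CDS start), score and optionally sigma_class.
    Malformed rows are rejected with their line numbers.  Per gene the
    nearest-upstream prediction is kept (largest offset; ties broken by
    highest score); the 5' UTR length is the negated offset and the
    summary reports its mean and standard deviation.
    """
    rows, bad = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for need in ("gene_id", "predicted_start_offset", "score"):
            if need not in idx:
                raise ValueError(f"{path}: missing column {need!r}")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            try:
                offset = float(parts[idx["predicted_start_offset"]])
                score = float(parts[idx["score"]])
                if not (np.isfinite(offset) and np.isfinite(score)):
                    raise ValueError
                rows.append(
                    {
                        "gene_id": parts[idx["gene_id"]],
                        "predicted_start_offset": offset,
                        "score": score,
                        "sigma_class": parts[idx["sigma_class"]]
                        if "sigma_class" in idx and len(parts) > idx["sigma_class"]
                        else "sigma70",
                    }
                )
            except (ValueError, IndexError):
                bad.append(ln)
    if bad:
        raise ValueError(f"{path}: malformed rows at lines {bad}")
    table = pd.DataFrame(rows)
    if table.empty:
        warnings.warn("empty promoter table: no UTR summary")
        return table, {"n": 0, "utr_mean": np.nan, "utr_sd": np.nan}
    best = (
        table.sort_values(["predicted_start_offset", "score"])
        .groupby("gene_id", sort=False)
        .tail(1)
    )
    utr = -best["predicted_start_offset"]
    return table, {
        "n": int(len(best)),
        "utr_mean": float(utr.mean()),
        "utr_sd": float(utr.std(ddof=1)) if len(best) > 1 else 0.0,
    }


def _load_or_synthesize(cfg: PipelineConfig):
    if cfg.fasta is not None:
        genome = genome_model.read_genome(cfg.fasta, cfg.annotation, cfg.tu_table)
        networks = {}
        if cfg.networks:
            df = pd.read_csv(cfg.networks, sep="\t", dtype=str)
            for kind, grp in df.groupby(df.columns[2]):
                networks[kind] = list(
                    zip(grp[df.columns[0]], grp[df.columns[1]])
                )
        return genome, networks, [], None, None
    if cfg.preset == "ecoli-like":
        spec = synthetic_data.ecoli_like(seed=cfg.seed, n_genes_ancestor=cfg.n_genes)
    else:
        spec = synthetic_data.buchnera_like(seed=cfg.seed, n_genes_ancestor=cfg.n_genes)
    ancestor, networks, transcriptons = synthetic_data.generate_ancestor(spec)
    sink_targets = [t[0] for t in transcriptons]
    ancestor = synthetic_data.plant_upstream_sinks(ancestor, spec, sink_targets)
    descendant, orthology = synthetic_data.derive_descendant(
        ancestor, spec, planted=transcriptons
    )
    return ancestor, networks, transcriptons, descendant, orthology


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the report directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=config.force or not out.exists())
    manifest = {
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("outdir",)
        },
        "status": "running",
    }
    t_all = time.time()
    state = {}

    def record(stage, status, t0):
        manifest["stages"][stage] = {
            "status": status, "wall_s": round(time.time() - t0, 3)
        }

    try:
        for stage in _ALL_STAGES:
            if stage not in config.stages:
                manifest["stages"][stage] = {"status": "skipped"}
                continue
            t0 = time.time()
            _STAGE_FNS[stage](config, state, out)
            record(stage, "done", t0)
    except Exception as exc:
        manifest["status"] = f"failed at {stage}: {exc}"
        _write_manifest(manifest, out)
        raise
    manifest["status"] = "ok"
    manifest["wall_s"] = round(time.time() - t_all, 3)
    _write_manifest(manifest, out)
    return out


def _write_manifest(manifest, out: Path):
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# --- stages ----------------------------------------------------------------

def _stage_synth(cfg, state, out: Path):
    genome, networks, transcriptons, descendant, orthology = _load_or_synthesize(cfg)
    state.update(
        genome=genome, networks=networks, transcriptons=transcriptons,
        descendant=descendant, orthology=orthology,
    )
    genome_model.write_genome_fasta(genome, out / "genome.fasta")
    genome_model.write_gene_table(genome, out / "genes.tsv")
    genome_model.write_tu_table(genome, out / "tus.tsv")
    if descendant is not None:
        genome_model.write_genome_fasta(descendant, out / "descendant.fasta")
        genome_model.write_gene_table(descendant, out / "descendant_genes.tsv")
        genome_model.write_orthology(orthology, out / "orthology.tsv")
    if cfg.promoters:
        table, summary = ingest_promoters(cfg.promoters)
        table.to_csv(out / "promoters_ingested.tsv", sep="\t", index=False)
        (out / "utr_summary.json").write_text(json.dumps(summary, indent=2))


def _stage_physics(cfg, state, out: Path):
    genome = state["genome"]
    seq = genome.sequence
    params = dna_physics.default_sidd_params(**cfg.sidd)
    tracks = {
        "stacking_energy": dna_physics.dinucleotide_profile(
            seq, dna_physics.load_dinucleotide_table("stacking_energy"),
            circular=genome.circular),
        "propeller_twist": dna_physics.dinucleotide_profile(
            seq, dna_physics.load_dinucleotide_table("propeller_twist"),
            circular=genome.circular),
        "curvature": dna_physics.curvature_profile(
            seq, dna_physics.load_wedge_model(), circular=genome.circular),
        "sidd": dna_physics.sidd_profile(seq, params, circular=genome.circular),
    }
    state["profiles"] = {}
    for name, per_base in tracks.items():
        prof = dna_physics.StructuralProfile(name, per_base, cfg.genome_window_bp)
        state["profiles"][name] = prof
        prof.to_tsv(out / f"profile_{name}.tsv")
    windows = genome_model.anchored_windows(genome, span_up=200, span_down=200)
    offsets, mean, n = dna_physics.aligned_mean_profile(
        genome, tracks["sidd"], windows
    )
    pd.DataFrame({"offset": offsets, "mean_sidd": mean, "n": n}).to_csv(
        out / "aligned_sidd.tsv", sep="\t", index=False
    )
    state["sidd_params"] = params


def _stage_nulls(cfg, state, out: Path):
    genome = state["genome"]
    for rep in range(cfg.null_replicates):
        seed = int(np.random.SeedSequence([cfg.seed % (2**31), 100 + rep])
                   .generate_state(1)[0] % (2**31))
        if cfg.null_kind == "global":
            shuffled = null_models.shuffle_global(genome, seed)
        else:
            shuffled = null_models.shuffle_local(genome, seed)
        genome_model.write_genome_fasta(
            shuffled, out / f"null_{cfg.null_kind}_{rep}.fasta",
            description=f"null={cfg.null_kind} seed={seed}",
        )


def _stage_scan(cfg, state, out: Path):
    genome = state["genome"]
    motifs, sigma32 = motif_scan.load_motifs()
    comp = np.array([genome.sequence.count(b) for b in "ACGT"], dtype=float)
    comp /= comp.sum()
    rows = []
    for m in motifs:
        hits = motif_scan.iupac_scan(genome.sequence, m, circular=genome.circular)
        expected = motif_scan.expected_hit_count(
            m, comp, len(genome), circular=genome.circular
        )
        z, p = motif_scan.representation_test(len(hits), expected)
        rows.append((m.name, m.iupac, len(hits), expected, z, p))
        motif_scan.hits_to_bed(hits, out / f"hits_{m.name}.bed", name=m.name,
                               chrom=genome.id)
    pd.DataFrame(
        rows, columns=["motif", "iupac", "observed", "expected", "z", "p"]
    ).to_csv(out / "motif_representation.tsv", sep="\t", index=False)
    upstream = {
        g.id: genome_model.upstream_region(genome, g.id, cfg.upstream_scan_bp)
        for g in genome.coding_genes()
    }
    n_two_box = sum(
        1 for seq in upstream.values()
        if motif_scan.two_box_scan(seq, sigma32, strands=("+",))
    )
    (out / "sigma32_scan.json").write_text(json.dumps({
        "genes_scanned": len(upstream),
        "genes_with_two_box_hit": n_two_box,
        "upstream_bp": cfg.upstream_scan_bp,
    }, indent=2))


def _stage_intergenic(cfg, state, out: Path):
    genome = state["genome"]
    sidd = state["profiles"]["sidd"].per_base
    regions = intergenic_analysis.classify_intergenic(genome)
    regions = intergenic_analysis.annotate_tu_relation(regions, genome.tus)
    stats_df = intergenic_analysis.region_profile_stats(
        regions, sidd, len(genome), statistic="mean"
    )
    stats_min = intergenic_analysis.region_profile_stats(
        regions, sidd, len(genome), statistic="min"
    )
    stats_df["value_min"] = stats_min["value"]
    stats_df.to_csv(out / "intergenic_stats.tsv", sep="\t", index=False)
    intergenic_analysis.regions_to_bed(
        regions, out / "intergenic.bed", len(genome), chrom=genome.id
    )
    pw = intergenic_analysis.promoter_window_values(
        genome, sidd, window_bp=cfg.promoter_window_bp
    )
    pd.DataFrame(
        [(s.gene_id, s.window_bp, s.value, s.truncated) for s in pw],
        columns=["gene_id", "window_bp", "value", "truncated"],
    ).to_csv(out / "promoter_windows.tsv", sep="\t", index=False)
    state["promoter_windows"] = pw
    tandem = stats_df.loc[stats_df.orientation_class == "tandem", "value"].dropna()
    if len(tandem) >= 10:
        verdict = intergenic_analysis.bimodality_assessment(
            tandem.to_numpy(), seed=cfg.seed % (2**31)
        )
        (out / "tandem_bimodality.json").write_text(
            json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in verdict.items()}, indent=2)
        )


def _stage_conserve(cfg, state, out: Path):
    genome, networks = state["genome"], state["networks"]
    descendant, orthology = state.get("descendant"), state.get("orthology")
    if not networks or descendant is None:
        warnings.warn("no networks/descendant available; conservation stage skipped")
        return
    gg = conservation_graphs.genome_neighbourhood_graph(genome, max_gap=5)
    report = {}
    kind_names = {"transcription": "transcripton", "ppi": "interacton",
                  "metabolic": "metabolon"}
    for net_kind, edges in networks.items():
        ng = conservation_graphs.network_neighbourhood_graph(edges, max_intermediate=1)
        comps = conservation_graphs.common_connected_components(
            gg, ng, kind=kind_names.get(net_kind, "synton")
        )
        cons = conservation_graphs.component_conservation(
            comps, descendant, orthology, max_gap=5
        )
        testable = sum(c["testable"] for c in cons)
        conserved = sum(c["conserved_as_component"] for c in cons)
        report[net_kind] = {
            "n_components": len(comps),
            "n_testable": testable,
            "n_conserved": conserved,
        }
        if net_kind == "transcription":
            sizes = [len(c.gene_set) for c in comps] or [2]
            res = conservation_graphs.r_transcripton_test(
                genome, sizes, orthology, descendant,
                observed_statistic=conserved,
                n_sims=cfg.resampling["n_sims"], cap=cfg.resampling["cap"],
                min_shared=cfg.resampling["min_shared"],
                span=cfg.resampling["span"], seed=cfg.seed % (2**31),
            )
            hist = np.bincount(res.null_statistics)
            report["r_transcripton_test"] = {
                "observed": res.observed_statistic,
                "p_value": res.p_value,
                "p_value_plus1": res.p_value_plus1,
                "n_sims": res.n_sims,
                "seed": res.seed,
                "null_histogram": hist.tolist(),
            }
    (out / "conservation.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    state["conservation"] = report


def _stage_stats(cfg, state, out: Path):
    genome = state["genome"]
    pw = state.get("promoter_windows")
    if pw is None:
        warnings.warn("no promoter windows computed; stats stage skipped")
        return
    values = {s.gene_id: s.value for s in pw}
    results = association_stats.rank_tests_all_categories(values, genome.categories)
    association_stats.results_to_frame(results).to_csv(
        out / "category_rank_tests.tsv", sep="\t", index=False
    )


_STAGE_FNS = {
    "synth": _stage_synth,
    "physics": _stage_physics,
    "nulls": _stage_nulls,
    "scan": _stage_scan,
    "intergenic": _stage_intergenic,
    "conserve": _stage_conserve,
    "stats": _stage_stats,
}
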