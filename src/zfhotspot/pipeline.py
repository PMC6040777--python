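"""End-to-end orchestration: annotate -> map -> positional tests -> context
tests -> gene stats -> enrichment -> report.

Each stage is a plain function over in-memory objects so the CLI subcommands
and the full run share one code path.  All tables are written as TSV with a
leading comment line carrying the tool version; the run manifest records the
seed and a hash of the configuration.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import __version__
from .domains import (domains_to_table, find_zf_domains, flag_tandem_neighbors,
                      intersect_with_hmm, parse_hmm_domain_table)
from .enrichment import (Network, estimate_qvalues, hypergeom_set_enrichment,
                         neat_interaction_enrichment, read_gmt)
from .errors import ConfigError, InputError
from .genestats import (compare_gene_sets, expression_iqr_fraction,
                        gene_rates_from_mutations, overlap_groups)
from .mapping import (aggregate_position_profile, map_mutations, read_gene_models,
                      read_maf)
from .models import LABELS, MISSENSE, label_to_index
from .positional import (Channel, build_gene_index, compute_context_rates,
                         context_rate_test, count_focal_channel_mutations,
                         count_focal_channel_sites, focal_codon_sites,
                         position_permutation_test, site_restricted_permutation)

log = logging.getLogger(__name__)

DEFAULT_CHANNELS = {9: [Channel("AGA", "T")],
                    11: [Channel("CCN", "T"), Channel("TCN", "T")]}


@dataclass
class PipelineConfig:
    """Paths and settings for a full run."""

    cohorts: dict                      # cohort_id -> {"maf": path}
    gene_model_table: str
    cds_fasta: str
    protein_fasta: str
    out_dir: str
    hmm_table: Optional[str] = None
    tpm: Optional[str] = None
    network: Optional[str] = None
    gmt: Optional[str] = None
    focal_labels: tuple = (9, 11)
    channels: dict = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    n_permutations: int = 10_000
    seed: int = 0
    qvalue_method: str = "storey"
    plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            gm = raw.pop("gene_models")
            cfg = cls(cohorts=raw.pop("cohorts"),
                      gene_model_table=gm["table"], cds_fasta=gm["cds_fasta"],
                      protein_fasta=gm["protein_fasta"],
                      out_dir=raw.pop("out_dir"), **{
                          k: v for k, v in raw.items()
                          if k in {"hmm_table", "tpm", "network", "gmt",
                                   "n_permutations", "seed", "qvalue_method",
                                   "plots", "log_level"}})
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc
        if "focal_labels" in raw:
            cfg.focal_labels = tuple(raw["focal_labels"])
        if "channels" in raw:
            cfg.channels = {int(lab): [Channel(c["context"], c["alt"]) for c in chans]
                            for lab, chans in raw["channels"].items()}
        return cfg

    def config_hash(self) -> str:
        def _clean(v):
            if isinstance(v, Channel):
                return {"context": v.context, "alt": v.alt}
            if isinstance(v, dict):
                return {str(k): _clean(x) for k, x in sorted(v.items(), key=lambda t: str(t[0]))}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v
        payload = json.dumps(_clean(vars(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# zfhotspot {__version__}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def annotate_stage(gene_models, hmm_table=None):
    """Scan all proteins for ZF domains; returns {gene_id: [ZFDomain]}."""
    domains = {}
    for gene_id, model in gene_models.items():
        found = find_zf_domains(model.protein_seq, gene_id=gene_id)
        if found:
            domains[gene_id] = found
    if hmm_table is not None:
        segments = parse_hmm_domain_table(hmm_table)
        domains = {g: intersect_with_hmm(d, segments) for g, d in domains.items()}
        domains = {g: d for g, d in domains.items() if d}
    for d in domains.values():
        flag_tandem_neighbors(d)
    return domains


def map_stage(maf_path, gene_models):
    """Read a MAF and annotate records onto the gene models."""
    records, skipped = read_maf(maf_path)
    mapped = map_mutations(records, gene_models)
    samples = sorted({m.sample_id for m in mapped})
    return mapped, samples, skipped


def focal_missense(mutations, domains, label):
    """Missense mutations falling at one focal label of any domain."""
    out = []
    for m in mutations:
        if m.gene_id not in domains or m.protein_pos is None or m.consequence != MISSENSE:
            continue
        for d in domains[m.gene_id]:
            if d.label_of_protein_pos(m.protein_pos) == label:
                out.append(m)
                break
    return out


def positional_stage(mutations, gene_models, domains, n_permutations, rng):
    zf_models = {g: gene_models[g] for g in domains}
    return position_permutation_test(mutations, zf_models, domains,
                                     n_permutations=n_permutations, rng=rng)


def concentration_stage(mutations, gene_models, domains, label,
                        n_permutations, rng):
    """Gene-concentration and KRAB-fraction site-restricted permutations."""
    zf_models = {g: gene_models[g] for g in domains}
    focal = focal_missense(mutations, domains, label)
    sites = focal_codon_sites(zf_models, domains, label)
    if not focal:
        return None
    return site_restricted_permutation(focal, sites, zf_models,
                                       n_permutations=n_permutations, rng=rng)


def context_stage(mutations, gene_models, domains, label, channels, samples):
    """Poisson-binomial test of focal channel mutations vs exome rates."""
    zf_models = {g: gene_models[g] for g in domains}
    rates, _ = compute_context_rates(mutations, gene_models, channels, samples)
    sites = focal_codon_sites(zf_models, domains, label)
    n_sites = count_focal_channel_sites(sites, channels)
    if n_sites == 0:
        raise InputError(f"no focal channel sites at label {label}")
    focal = focal_missense(mutations, domains, label)
    observed = count_focal_channel_mutations(focal, gene_models, channels)
    return context_rate_test(n_sites, rates, observed, channels)


def gene_stats_stage(mutations, gene_models, domains, focal_genes, n_samples,
                     focal_labels):
    """Normalized ns/s ratio comparison of focal ZF genes vs other mutated genes."""
    cds = {g: m.cds_seq for g, m in gene_models.items()}
    focal_positions = {}
    for g, doms in domains.items():
        pos = set()
        for d in doms:
            for lab in focal_labels:
                pos.add(d.protein_start + label_to_index(lab) - 1)
        focal_positions[g] = pos
    rates = gene_rates_from_mutations(mutations, cds, n_samples,
                                      focal_positions=focal_positions)
    focal_ratios = [rates[g].normalized_ratio for g in focal_genes if g in rates]
    other = [r.normalized_ratio for g, r in rates.items()
             if g not in focal_genes and r.missense_count >= 1
             and r.synonymous_count >= 1]
    p_ratio = None
    focal_def = [v for v in focal_ratios if v is not None]
    other_def = [v for v in other if v is not None]
    if focal_def and other_def:
        p_ratio = compare_gene_sets(focal_def, other_def, alternative="greater")
    return rates, p_ratio


def per_sample_focal_counts(profile, label):
    """Per-sample focal counts sorted high to low, plus Spearman r against
    total ZF-domain missense burden."""
    counts = profile.per_sample[label]
    total = profile.per_sample.sum(axis=1)
    sorted_counts = counts.sort_values(ascending=False)
    mask = counts > 0
    if mask.sum() >= 3 and total[mask].nunique() > 1:
        rho = float(sstats.spearmanr(counts[mask], total[mask]).statistic)
    else:
        rho = float("nan")
    return sorted_counts, rho


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for every cohort; returns the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    results: dict = {"cohorts": {}, "config_hash": config.config_hash(),
                     "seed": config.seed}
    try:
        gene_models = read_gene_models(config.gene_model_table, config.cds_fasta,
                                       config.protein_fasta)
        tpm = pd.read_csv(config.tpm, sep="\t", comment="#", index_col=0) \
            if config.tpm else None
        network = Network.from_tsv(config.network) if config.network else None
        annotation_sets = read_gmt(config.gmt) if config.gmt else None

        stage = "annotate"
        domains = annotate_stage(gene_models, config.hmm_table)
        dom_table = domains_to_table(
            [d for ds in domains.values() for d in ds])
        _write_tsv(dom_table, out / "domains.tsv")
        results["n_zf_genes"] = len(domains)
        results["n_domains"] = sum(len(d) for d in domains.values())

        rng = np.random.default_rng(config.seed)
        focal_gene_sets: dict[str, set] = {}
        for cohort_id, spec in config.cohorts.items():
            cres: dict = {}
            stage = f"{cohort_id}:map"
            mutations, samples, skipped = map_stage(spec["maf"], gene_models)
            cres["n_samples"] = len(samples)
            cres["n_mutations"] = len(mutations)
            cres["skipped_variants"] = dict(skipped)

            stage = f"{cohort_id}:profile"
            profile = aggregate_position_profile(
                mutations, domains, samples, cohort_id=cohort_id,
                gene_models=gene_models, focal_labels=config.focal_labels)
            profile.validate()
            cres["profile"] = profile
            prof_df = pd.DataFrame({
                "label": list(LABELS),
                "missense": [profile.counts[l] for l in LABELS],
                "synonymous": [profile.synonymous_counts[l] for l in LABELS],
                "per_sample_average": [profile.per_sample_average[l] for l in LABELS]})
            _write_tsv(prof_df, out / f"{cohort_id}.position_profile.tsv")
            _write_tsv(profile.per_sample, out / f"{cohort_id}.per_sample_matrix.tsv",
                       index=True)

            stage = f"{cohort_id}:positional-tests"
            perms = positional_stage(mutations, gene_models, domains,
                                     config.n_permutations, rng)
            cres["positional"] = perms
            _write_tsv(pd.DataFrame([{
                "label": lab, "observed": r.observed, "null_mean": r.null_mean,
                "fold": r.fold, "empirical_p": r.empirical_p,
                "p_display": r.p_display, "n_permutations": r.n_permutations}
                for lab, r in perms.items()]),
                out / f"{cohort_id}.positional_tests.tsv")

            cres["concentration"] = {}
            cres["context"] = {}
            cres["per_sample_focal"] = {}
            for label in config.focal_labels:
                stage = f"{cohort_id}:concentration-label{label}"
                conc = concentration_stage(mutations, gene_models, domains,
                                           label, config.n_permutations, rng)
                cres["concentration"][label] = conc
                stage = f"{cohort_id}:context-label{label}"
                channels = config.channels.get(label, [])
                if channels:
                    cres["context"][label] = context_stage(
                        mutations, gene_models, domains, label, channels, samples)
                sorted_counts, rho = per_sample_focal_counts(profile, label)
                cres["per_sample_focal"][label] = {
                    "sorted_counts": sorted_counts, "spearman_vs_total": rho}

            stage = f"{cohort_id}:gene-stats"
            focal_genes = set()
            for label in config.focal_labels:
                focal_genes |= {m.gene_id for m in
                                focal_missense(mutations, domains, label)}
            focal_gene_sets[cohort_id] = focal_genes
            rates, p_ratio = gene_stats_stage(
                mutations, gene_models, domains, focal_genes, len(samples),
                config.focal_labels)
            cres["focal_genes"] = focal_genes
            cres["ratio_comparison_p"] = p_ratio
            _write_tsv(pd.DataFrame([{
                "gene_id": r.gene_id, "ns_sites": r.ns_sites, "s_sites": r.s_sites,
                "missense": r.missense_count, "synonymous": r.synonymous_count,
                "missense_rate_per_base": r.missense_rate_per_base,
                "normalized_ratio": r.normalized_ratio}
                for r in rates.values()]), out / f"{cohort_id}.gene_rates.tsv")

            if tpm is not None:
                stage = f"{cohort_id}:expression"
                pairs = set()
                for label in config.focal_labels:
                    for m in focal_missense(mutations, domains, label):
                        pairs.add((m.gene_id, m.sample_id))
                cres["iqr_fraction"] = expression_iqr_fraction(tpm, pairs)

            if annotation_sets is not None:
                stage = f"{cohort_id}:enrichment"
                background = set(gene_models)
                enr = hypergeom_set_enrichment(focal_genes, annotation_sets,
                                               background)
                if len(enr):
                    enr["q"] = estimate_qvalues(enr["p"].to_numpy(),
                                                method=config.qvalue_method)
                _write_tsv(enr, out / f"{cohort_id}.set_enrichment.tsv")
                cres["set_enrichment"] = enr
                if network is not None:
                    rows = []
                    for aset in annotation_sets:
                        obs, exp, p = neat_interaction_enrichment(
                            focal_genes, aset.members, network)
                        rows.append({"set_id": aset.set_id, "term": aset.term_name,
                                     "links": obs, "expected": exp, "p": p})
                    neat = pd.DataFrame(rows)
                    if len(neat):
                        neat["q"] = estimate_qvalues(neat["p"].to_numpy(),
                                                     method=config.qvalue_method)
                        neat = neat.sort_values(["p", "set_id"]).reset_index(drop=True)
                    _write_tsv(neat, out / f"{cohort_id}.neat_enrichment.tsv")
                    cres["neat"] = neat

            if config.plots:
                stage = f"{cohort_id}:plots"
                _plot_profile(profile, out / f"{cohort_id}.profile.png")

            results["cohorts"][cohort_id] = cres

        if len(focal_gene_sets) > 1:
            stage = "overlap-groups"
            groups = overlap_groups(focal_gene_sets)
            results["overlap_groups"] = groups
            rows = [{"signature": "+".join(sig), "gene": e["gene"]}
                    for sig, entries in groups.items() for e in entries]
            _write_tsv(pd.DataFrame(rows, columns=["signature", "gene"]),
                       out / "overlap_groups.tsv")

        stage = "report"
        report = write_report(results)
        (out / "report.txt").write_text(report)
        manifest = {"seed": config.seed, "config_hash": results["config_hash"],
                    "version": __version__,
                    "n_permutations": config.n_permutations}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    return results


class StageFailure(Exception):
    """Wraps any stage error with the stage name for CLI reporting."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _plot_profile(profile, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    labels = list(LABELS)
    ax.bar(range(21), [profile.per_sample_average[l] for l in labels])
    ax.set_xticks(range(21), [str(l) for l in labels], fontsize=7)
    ax.set_xlabel("domain position (helix-relative)")
    ax.set_ylabel("missense / sample")
    ax.set_title(profile.cohort_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_report(results: dict) -> str:
    """Render a deterministic human-readable summary of a result bundle."""
    lines = [f"zfhotspot report (seed {results.get('seed')}, "
             f"config {results.get('config_hash')})",
             f"ZF genes: {results.get('n_zf_genes', 0)}   "
             f"domains: {results.get('n_domains', 0)}", ""]
    for cohort_id in sorted(results.get("cohorts", {})):
        c = results["cohorts"][cohort_id]
        lines.append(f"=== {cohort_id} ===")
        lines.append(f"samples: {c['n_samples']}   mutations: {c['n_mutations']}")
        profile = c.get("profile")
        if profile is not None and sum(profile.counts.values()) == 0:
            lines.append("zero ZF-domain mutations in this cohort")
        perms = c.get("positional", {})
        if perms:
            ranked = sorted(perms.items(),
                            key=lambda kv: (kv[1].empirical_p, -kv[1].observed))
            lines.append("top domain labels (observed, fold, empirical p):")
            for lab, r in ranked[:3]:
                lines.append(f"  label {lab:>3}: obs={r.observed:.0f} "
                             f"fold={r.fold:.2f} p={r.p_display}")
        for label, conc in sorted(c.get("concentration", {}).items()):
            if conc is None:
                lines.append(f"label {label}: no focal mutations")
                continue
            g = conc["n_distinct_genes"]
            k = conc["krab_fraction"]
            lines.append(f"label {label}: genes hit {g.observed:.0f} "
                         f"(null mean {g.null_mean:.1f}, lower-tail p={g.p_display}); "
                         f"KRAB fraction {k.observed:.2f} "
                         f"(null mean {k.null_mean:.2f}, upper-tail p={k.p_display})")
        for label, ct in sorted(c.get("context", {}).items()):
            lines.append(f"label {label} context test: obs={ct.observed} "
                         f"expected={ct.expected:.2f} fold={ct.fold:.1f} "
                         f"p={ct.p_value:.3g}")
        for label, ps in sorted(c.get("per_sample_focal", {}).items()):
            lines.append(f"label {label} Spearman(focal count, total burden) = "
                         f"{ps['spearman_vs_total']:.3f}")
        if c.get("ratio_comparison_p") is not None:
            lines.append(f"ns/s normalized-ratio comparison (focal vs other "
                         f"mutated genes, one-sided MW): p={c['ratio_comparison_p']:.3g}")
        if c.get("iqr_fraction") is not None:
            lines.append(f"expression IQR membership of mutated pairs: "
                         f"{c['iqr_fraction']:.2f}")
        enr = c.get("set_enrichment")
        if enr is not None and len(enr):
            top = enr.iloc[0]
            lines.append(f"top annotation term: {top['term']} "
                         f"(overlap {top['overlap']}, p={top['p']:.3g}, q={top['q']:.3g})")
        lines.append("")
    groups = results.get("overlap_groups")
    if groups:
        lines.append("gene-set overlap groups:")
        for sig in sorted(groups, key=lambda s: (len(s), s)):
            if groups[sig]:
                genes = ", ".join(e["gene"] for e in groups[sig])
                lines.append(f"  {'+'.join(sig)}: {genes}")
    return "\n".join(lines) + "\n"
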