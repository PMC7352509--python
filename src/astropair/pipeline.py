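"""End-to-end pipeline over a simulated (or ingested) cohort.

Stage order: simulate -> preprocess -> copy number -> clustering ->
differential expression -> HMM state calling -> subtype assignment ->
progression aggregation -> mutation summaries. Every artifact is a
plain-text TSV/JSON file and the run closes with a checksum manifest, so a
fixed seed reproduces the output directory byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, cnv, de, hmm, io, mutations, preprocess, progression
from .params import HMMParams
from .subtype import (
    CentroidSubtypeClassifier,
    gcimp_call,
    transition_table,
    tumor_logratio_vs_normal,
)
from .synthetic_data import (
    CohortSpec,
    pairs_table,
    simulate_cohort,
    simulate_pair_profiles,
    simulate_variant_tables,
    synthetic_annotations,
)

log = logging.getLogger("astropair")


@dataclass
class PipelineConfig:
    """Validated stage parameters; unknown keys are rejected on load."""

    seed: int = 0
    out_dir: str = "astropair_run"
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    cpm_offset: float = 0.5
    loess_span: float = 0.7
    loess_cycles: int = 3
    n_clusters: int = 3
    bootstrap_replicates: int = 100
    q_threshold: float = 0.01
    min_fraction: float = 0.5
    loss_cut: float = cnv.DEFAULT_LOSS_CUT
    gain_cut: float = cnv.DEFAULT_GAIN_CUT
    min_event_fraction: float = cnv.DEFAULT_MIN_FRACTION
    hmm_means_init: tuple = (-3.0, 0.0, 3.0)
    hmm_self_transition: float = 0.9
    hmm_tol: float = 1e-4
    hmm_max_iter: int = 200
    hmm_tied_variance: bool = False
    concat_genome: bool = False  # chain across chromosome boundaries
    mutation_scope: str = "shared-in-pair"
    min_r: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort = d.get("cohort", {})
        spec_fields = {f.name for f in fields(CohortSpec)}
        bad = set(cohort) - spec_fields
        if bad:
            raise ValueError(f"unknown cohort keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**{**self.cohort, "seed": self.seed})


def run_pipeline(
    config: PipelineConfig, out_dir: str | None = None, seed: int | None = None
) -> Path:
    """Execute every stage on a freshly simulated cohort; returns the
    manifest path. ``out_dir``/``seed`` override the config's values."""
    if seed is not None:
        config.seed = int(seed)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info("seed=%d out=%s", config.seed, out)
    written: list[Path] = []

    def save_matrix(df, name, index_label="gene"):
        p = out / name
        io.write_matrix(df.round(6), p, index_label=index_label)
        written.append(p)

    def save_table(df, name):
        p = out / name
        io.write_table(df, p)
        written.append(p)

    def save_json(obj, name):
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        written.append(p)

    # effective config echo (provenance)
    save_json(asdict(config), "config.json")

    # ---- simulate ----------------------------------------------------------
    spec = config.cohort_spec()
    cohort = simulate_cohort(spec)
    profiles_hmm, hmm_truth = simulate_pair_profiles(spec, cohort.gene_map)
    variants, variant_truth = simulate_variant_tables(spec, cohort.gene_map)
    annotations = synthetic_annotations(cohort.gene_map, seed=spec.seed)
    save_table(cohort.gene_map, "gene_map.tsv")
    save_matrix(cohort.counts, "counts.tsv")
    save_table(cohort.sample_sheet, "sample_sheet.tsv")
    segp = out / "segments.seg"
    io.write_seg(cohort.segments, segp)
    written.append(segp)
    gmtp = out / "signatures.gmt"
    io.write_weighted_gmt(cohort.signatures, gmtp)
    written.append(gmtp)
    for pat, (ini, rec) in variants.items():
        for callset, tag in ((ini, "initial"), (rec, "recurrent")):
            p = out / f"variants_{pat}_{tag}.vcf"
            io.write_vcf(callset, p)
            written.append(p)

    # ---- preprocess --------------------------------------------------------
    counts = preprocess.filter_low_expression(cohort.counts)
    logexpr = preprocess.log_cpm(counts, offset=config.cpm_offset)
    logexpr = preprocess.cyclic_loess_normalize(
        logexpr, span=config.loess_span, n_cycles=config.loess_cycles
    )
    save_matrix(logexpr, "logexpr_normalized.tsv")
    gene_map = cohort.gene_map[cohort.gene_map["gene"].isin(logexpr.index)]

    sheet = cohort.sample_sheet
    normals = sheet.loc[sheet["role"] == "normal", "sample"].tolist()
    tumors = sheet.loc[sheet["role"] != "normal", "sample"].tolist()
    pairs = pairs_table(sheet)

    # ---- copy number -------------------------------------------------------
    cn_profiles = cnv.segments_to_genes(cohort.segments, cohort.gene_map)
    save_matrix(cn_profiles, "cn_gene_profiles.tsv")
    events = cnv.call_events(
        cn_profiles, cohort.gene_map,
        loss_cut=config.loss_cut, gain_cut=config.gain_cut,
        min_fraction=config.min_event_fraction,
    )
    save_table(events, "cn_event_calls.tsv")

    # ---- clustering (copy number, then expression) -------------------------
    results_cluster = {}
    for name, X, ids in (
        ("cn", cn_profiles.T.to_numpy(), list(cn_profiles.columns)),
        ("expr", logexpr[tumors].T.to_numpy(), tumors),
    ):
        model = clustering.WardCorrelationClustering(config.n_clusters)
        model.fit(X, sample_ids=ids)
        save_table(
            model.labels_.rename_axis("sample").reset_index(),
            f"clusters_{name}.tsv",
        )
        adjacency = model.pair_adjacency(
            pairs[["initial", "recurrent"]].itertuples(index=False, name=None)
        )
        save_table(adjacency, f"pair_adjacency_{name}.tsv")
        support = model.bootstrap_support(
            B=config.bootstrap_replicates, seed=config.seed
        )
        save_table(
            pd.DataFrame({"node": np.arange(support.size), "support": support}),
            f"bootstrap_support_{name}.tsv",
        )
        results_cluster[name] = model
        # per-subgroup average copy-number profiles
        if name == "cn":
            avg = {
                f"cluster_{c}": cnv.average_profile(
                    cn_profiles[model.labels_.index[model.labels_ == c]]
                )
                for c in sorted(model.labels_.unique())
            }
            save_matrix(pd.DataFrame(avg), "cn_average_profiles.tsv")

    # ---- differential expression vs normal references ----------------------
    expr_labels = results_cluster["expr"].labels_
    de_results = {}
    for c in sorted(expr_labels.unique()):
        members = expr_labels.index[expr_labels == c].tolist()
        res = de.moderated_two_group_test(
            logexpr, members, normals, q_threshold=config.q_threshold
        )
        de_results[f"cluster_{c}"] = res
        save_matrix(res, f"de_cluster_{c}.tsv")
    venn = de.de_sets_and_venn(de_results, threshold=config.q_threshold)
    save_json(venn["venn"], "de_venn.json")
    enrich = {
        name: de.category_enrichment(
            sets["over"] | sets["under"], logexpr.index, annotations
        )["p"].to_dict()
        for name, sets in venn["sets"].items()
    }
    save_json(enrich, "de_enrichment.json")

    # ---- HMM state calling -------------------------------------------------
    expr_pairs = hmm.pair_logratio(logexpr, pairs)
    chrom = (
        np.zeros(len(gene_map), dtype=int)
        if config.concat_genome
        else gene_map["chrom"].to_numpy()
    )
    init = HMMParams(
        startprob=np.full(3, 1 / 3),
        transmat=np.full((3, 3), (1 - config.hmm_self_transition) / 2)
        + np.eye(3) * (config.hmm_self_transition - (1 - config.hmm_self_transition) / 2),
        means=np.asarray(config.hmm_means_init, dtype=float),
        variances=np.ones(3),
    )
    params, trace = hmm.fit_hmm(
        expr_pairs, chrom, init=init,
        max_iter=config.hmm_max_iter, tol=config.hmm_tol,
        tied_variance=config.hmm_tied_variance,
        means_init=config.hmm_means_init,
        self_transition=config.hmm_self_transition,
    )
    params.to_json(out / "hmm_params.json")
    written.append(out / "hmm_params.json")
    posteriors, labels = hmm.posterior_decode(expr_pairs, chrom, params)
    save_matrix(labels, "hmm_state_calls.tsv")
    decoded_long = pd.concat(
        {p: g.round(6) for p, g in posteriors.items()}, names=["patient", "gene"]
    ).reset_index()
    save_table(decoded_long, "hmm_posteriors.tsv")

    # ---- subtype assignment ------------------------------------------------
    logratio = tumor_logratio_vs_normal(logexpr, normals)
    class_sigs = [s for s in cohort.signatures if s.name != "G-CIMP"]
    gcimp_sig = next(s for s in cohort.signatures if s.name == "G-CIMP")
    clf = CentroidSubtypeClassifier(class_sigs, min_r=config.min_r)
    calls = clf.predict(logratio)
    corrs = clf.correlations(logratio)
    gcimp = pd.DataFrame(
        {
            s: gcimp_call(logratio[s], gcimp_sig)
            for s in logratio.columns
        },
        index=["r", "positive"],
    ).T
    subtype_table = pd.concat(
        [calls.rename("verhaak_class"), corrs, gcimp], axis=1
    )
    save_matrix(subtype_table, "subtype_calls.tsv", index_label="sample")
    trans, excluded = transition_table(calls, pairs)
    save_matrix(trans, "subtype_transitions.tsv", index_label="initial_class")
    save_json({"excluded_pairs": excluded}, "subtype_excluded.json")

    # ---- progression aggregation -------------------------------------------
    groups = (
        pairs.merge(sheet[["patient", "group"]].drop_duplicates(), on="patient")
        .groupby("group")["patient"]
        .apply(list)
        .to_dict()
    )
    counts_summary = progression.group_alteration_counts(labels, groups)
    save_matrix(
        counts_summary.set_axis(
            ["|".join(c) for c in counts_summary.columns], axis=1
        ),
        "progression_counts.tsv",
    )
    freq = progression.frequent_sets(counts_summary, config.min_fraction)
    save_json(
        {
            "venn": freq["venn"],
            "opposite": freq["opposite"],
            "set_sizes": {
                g: {d: len(s) for d, s in ds.items()}
                for g, ds in freq["sets"].items()
            },
        },
        "progression_frequent_sets.json",
    )
    avg_profiles = {}
    for g, ds in freq["sets"].items():
        for d in ("under", "over"):
            prof = progression.average_alteration_profile(
                expr_pairs, labels, groups[g], ds[d], d
            )
            avg_profiles[f"{g}|{d}"] = prof
    save_matrix(
        pd.DataFrame(avg_profiles).reindex(expr_pairs.index).dropna(how="all"),
        "progression_average_profiles.tsv",
    )
    pathway_sets = {k: v for k, v in annotations.items() if k.startswith("pathway")}
    pathways = progression.pathway_alteration_profile(
        freq["sets"], pathway_sets, logexpr.index
    )
    save_table(pathways.round(6), "progression_pathways.tsv")

    # ---- mutation summaries ------------------------------------------------
    shared_rows = []
    tallies = []
    for pat, (ini, rec) in variants.items():
        s, ip, rp = mutations.shared_private(ini, rec)
        shared_rows.append((pat, s, ip, rp))
        for tag, callset in (("initial", ini), ("recurrent", rec)):
            tallies.append({"patient": pat, "tumor": tag,
                            **mutations.functional_tally(callset)})
    save_table(
        pd.DataFrame(
            shared_rows,
            columns=["patient", "n_shared", "n_initial_private",
                     "n_recurrent_private"],
        ),
        "variants_shared_private.tsv",
    )
    save_table(pd.DataFrame(tallies), "variants_functional_tally.tsv")
    for scope in ("shared-in-pair", "any-sample"):
        freq_table = mutations.gene_frequency(variants, scope=scope, groups=groups)
        save_matrix(
            freq_table.round(6).head(50),
            f"gene_mutation_frequency_{scope.replace('-', '_')}.tsv",
            index_label="gene",
        )

    manifest = io.write_manifest(out, written, meta={"seed": config.seed})
    log.info("pipeline complete: %s", manifest)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
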