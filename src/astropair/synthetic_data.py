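"""Synthetic patient-matched cohorts with planted ground truth.

Every downstream stage is testable without external data: the generator
plants (i) segmental copy-number events that shift the expression of the
genes they contain, (ii) three copy-number and three expression subgroups,
(iii) subtype centroid structure with initial->recurrent class switches,
(iv) per-pair chromosomally ordered expression-state runs drawn from a known
three-state HMM, and (v) paired somatic variant sets with shared and private
calls, including genes recurrently mutated across pairs.

Randomness uses numpy's PCG64 via SeedSequence substreams keyed by (stream,
sample-or-pair index), so a fixed seed gives bit-identical output and adding
samples does not perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import HMMParams
from .subtype import SubtypeSignature

# named RNG substreams
_S_BASELINE, _S_NOISE, _S_SEG, _S_VARIANT, _S_COUNTS, _S_CENTROID, _S_HMM = range(7)

DEFAULT_GROUP_SIZES = {"A2->A3": 6, "A2->G4": 5, "A3->G4": 10}
SUBTYPE_CLASSES = ("neural", "proneural", "classical", "mesenchymal")
# planted initial -> recurrent switches (proneural tumors recur mesenchymal)
DEFAULT_SUBTYPE_TRANSITIONS = {
    "proneural": "mesenchymal",
    "classical": "classical",
    "mesenchymal": "mesenchymal",
}
FUNC_CLASS_PROBS = {
    "nonsynonymous": 0.30,
    "stop": 0.04,
    "synonymous": 0.14,
    "intronic": 0.44,
    "other": 0.08,
}


def _rng(seed: int, stream: int, index: int | None = None) -> np.random.Generator:
    key = (stream,) if index is None else (stream, index)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class CNAEvent:
    """A planted copy-number event.

    stage selects which member of a pair carries it ('both', 'initial',
    'recurrent'); subgroup=None plants it in every copy-number subgroup.
    """

    chrom: str
    start: int
    end: int
    log2_ratio: float
    subgroup: int | None = None
    stage: str = "both"


def default_cna_events(n_chromosomes: int, chrom_length: int) -> list[CNAEvent]:
    """Subgroup-defining whole/half-chromosome events plus a recurrent-only
    deletion of the last chromosome (the chromosome-10-like progression
    event, acquired at relapse by the patients of one subgroup)."""
    L = chrom_length
    ev = [
        CNAEvent("chr1", 0, L, -1.0, subgroup=0),
        CNAEvent("chr2", 0, L, 1.0, subgroup=0),
        CNAEvent("chr3", 0, L, 1.0, subgroup=1),
        CNAEvent("chr4", 0, L // 2, -1.0, subgroup=1),
        CNAEvent("chr5", 0, L, -1.0, subgroup=2),
        CNAEvent("chr6", L // 2, L, 1.0, subgroup=2),
    ]
    last = f"chr{n_chromosomes}"
    ev.append(CNAEvent(last, 0, L, -1.0, subgroup=0, stage="recurrent"))
    return [e for e in ev if int(e.chrom[3:]) <= n_chromosomes]


@dataclass
class CohortSpec:
    """Study conditions of the simulated patient-matched cohort.

    Defaults mirror the emulated study at desk scale: 21 patient-matched
    pairs in three progression groups (6 A2->A3, 5 A2->G4, 10 A3->G4), four
    normal brain references, a three-state HMM with emission means (-3, 0, 3),
    emission sd 0.7 and self-transition 0.9, and per-pair variant loads of on
    average 60 shared, 106 initial-private and 173 recurrent-private calls.
    """

    n_patients: int = 21
    n_genes: int = 2000
    n_chromosomes: int = 10
    chrom_length: int = 10_000_000
    progression_groups: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    hmm_truth: HMMParams = field(
        default_factory=lambda: HMMParams(
            startprob=np.full(3, 1 / 3),
            transmat=np.full((3, 3), 0.05) + np.eye(3) * 0.85,
            means=np.array([-3.0, 0.0, 3.0]),
            variances=np.full(3, 0.49),
        )
    )
    cna_truth: list | None = None  # None -> default_cna_events
    cna_attenuation: float = 0.5  # dosage damping of DNA ratio -> expression
    expr_subgroup_effect: float = 2.0  # log2 shift of subgroup marker blocks
    n_subgroup_genes: int = 150  # marker block size per expression subgroup
    signature_effect: float = 2.0  # sd of subtype centroid weights (log2)
    n_signature_genes: int = 50  # signature panel size per class
    subtype_transitions: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_TRANSITIONS)
    )
    variant_truth: dict | None = None  # patient -> (shared, init_priv, rec_priv)
    variant_means: tuple = (60, 106, 173)
    mutated_gene_truth: dict | None = None  # gene slot -> fraction of pairs
    n_normals: int = 4
    noise_sd: float = 0.5  # per-gene expression noise, log2 units
    within_pair_sd: float = 0.25  # patient-level shared expression effect
    cn_noise_sd: float = 0.1  # per-sample segment-mean noise
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    library_size: int = 5_000_000
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_genes < self.n_chromosomes:
            raise ValueError("n_genes must be >= n_chromosomes")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if sum(self.progression_groups.values()) != self.n_patients:
            raise ValueError("progression group sizes must sum to n_patients")
        self.hmm_truth.validate()
        for e in self.events():
            if e.chrom not in {f"chr{i + 1}" for i in range(self.n_chromosomes)}:
                raise ValueError(f"event chromosome {e.chrom} outside cohort")
            if not (0 <= e.start < e.end <= self.chrom_length):
                raise ValueError("planted event span outside chromosome bounds")
        return self

    def events(self) -> list[CNAEvent]:
        if self.cna_truth is not None:
            return list(self.cna_truth)
        return default_cna_events(self.n_chromosomes, self.chrom_length)


@dataclass
class SimTruth:
    """Planted ground truth of a simulated cohort."""

    subgroup: pd.Series | None = None  # sample -> copy-number subgroup
    expr_subgroup: pd.Series | None = None  # sample -> expression subgroup
    subtype: pd.Series | None = None  # sample -> planted class
    gcimp: pd.Series | None = None  # sample -> planted G-CIMP positivity
    expr_mean: pd.DataFrame | None = None  # noiseless log2 expression
    hmm_states: pd.DataFrame | None = None  # genes x patients state codes
    variant_counts: dict | None = None  # patient -> (shared, ip, rp)
    variant_keys: dict | None = None  # patient -> dict of key sets
    mutated_gene_truth: dict | None = None  # gene -> planted pair fraction


@dataclass
class SimulatedCohort:
    gene_map: pd.DataFrame
    logexpr: pd.DataFrame
    counts: pd.DataFrame
    segments: pd.DataFrame
    sample_sheet: pd.DataFrame
    signatures: list
    truth: SimTruth


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------

def build_gene_map(spec: CohortSpec) -> pd.DataFrame:
    """Evenly spaced, non-overlapping gene coordinates over the chromosomes.

    Genes are distributed as evenly as possible (remainder to the first
    chromosomes), coordinates are strictly increasing within a chromosome,
    and a total chromosomal order index 0..n_genes-1 is assigned.
    """
    spec.validate()
    per = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per[: spec.n_genes % spec.n_chromosomes] += 1
    rows = []
    order = 0
    for c in range(spec.n_chromosomes):
        m = int(per[c])
        if m == 0:
            continue
        pitch = spec.chrom_length // m
        width = max(1, pitch // 2)
        for i in range(m):
            start = i * pitch
            rows.append(
                (f"g{order + 1:05d}", f"chr{c + 1}", start, start + width, order)
            )
            order += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "order"])


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _patient_table(spec: CohortSpec) -> pd.DataFrame:
    rows = []
    i = 0
    for label, count in spec.progression_groups.items():
        initial_grade, recurrent_grade = label.split("->")
        for _ in range(count):
            rows.append((f"P{i + 1:02d}", label, initial_grade, recurrent_grade))
            i += 1
    return pd.DataFrame(
        rows, columns=["patient", "group", "initial_grade", "recurrent_grade"]
    )


def _subtype_blocks(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Disjoint signature gene index blocks (classes + G-CIMP) at the tail."""
    k = spec.n_signature_genes
    panels = list(SUBTYPE_CLASSES) + ["G-CIMP"]
    total = k * len(panels)
    start = spec.n_genes - total
    if start < 3 * spec.n_subgroup_genes:
        raise ValueError("not enough genes for subgroup and signature blocks")
    return {
        cls: np.arange(start + i * k, start + (i + 1) * k)
        for i, cls in enumerate(panels)
    }


def _make_signatures(spec: CohortSpec, gene_map: pd.DataFrame) -> list:
    blocks = _subtype_blocks(spec)
    rng = _rng(spec.seed, _S_CENTROID)
    sigs = []
    for cls in list(SUBTYPE_CLASSES) + ["G-CIMP"]:
        idx = blocks[cls]
        weights = rng.normal(0.0, spec.signature_effect, size=idx.size)
        sigs.append(
            SubtypeSignature(
                cls, pd.Series(weights, index=gene_map["gene"].to_numpy()[idx])
            )
        )
    return sigs


def _sample_segments(
    spec: CohortSpec,
    boundary_events: list[CNAEvent],
    carried: list[CNAEvent],
    pair_noise: list[float],
    rng: np.random.Generator,
) -> list[tuple[str, int, int, float]]:
    """Non-overlapping segments covering every chromosome.

    Boundaries come from the union of the patient's events (so initial and
    recurrent samples share a segmentation); values from the carried events
    plus a patient-shared noise term and a smaller per-sample term.
    """
    segs = []
    i = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        cuts = {0, spec.chrom_length}
        for e in boundary_events:
            if e.chrom == chrom:
                cuts |= {e.start, e.end}
        bounds = sorted(cuts)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            value = 0.0
            for e in carried:
                if e.chrom == chrom and e.start <= lo and hi <= e.end:
                    value += e.log2_ratio
            value += pair_noise[i] + rng.normal(0, spec.cn_noise_sd / 3.0)
            i += 1
            segs.append((chrom, lo, hi, value))
    return segs


def _segment_count(spec: CohortSpec, boundary_events: list[CNAEvent]) -> int:
    n = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        cuts = {0, spec.chrom_length}
        for e in boundary_events:
            if e.chrom == chrom:
                cuts |= {e.start, e.end}
        n += len(cuts) - 1
    return n


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the full cohort: expression, counts, segments, metadata, truth."""
    spec.validate()
    gene_map = build_gene_map(spec)
    patients = _patient_table(spec)
    genes = gene_map["gene"].to_numpy()
    n = spec.n_genes

    baseline = _rng(spec.seed, _S_BASELINE).normal(
        spec.baseline_mean, spec.baseline_sd, size=n
    )

    # per-patient planted labels
    n_pat = len(patients)
    subgroup = np.arange(n_pat) % 3
    thirds = np.repeat([0, 1, 2], int(np.ceil(n_pat / 3)))[:n_pat]
    expr_subgroup = (np.arange(n_pat) + thirds) % 3
    planted_classes = [c for c in SUBTYPE_CLASSES if c != "neural"]
    initial_subtype = [planted_classes[i % 3] for i in range(n_pat)]
    recurrent_subtype = [spec.subtype_transitions[c] for c in initial_subtype]
    # classical pairs play the IDH1-wild-type role: planted G-CIMP negative
    gcimp_positive = [c != "classical" for c in initial_subtype]

    blocks = _subtype_blocks(spec)
    signatures = _make_signatures(spec, gene_map)
    sig_weights = {
        s.name: (blocks[s.name], s.centroid.to_numpy()) for s in signatures
    }

    events = spec.events()
    mid = (gene_map["start"].to_numpy() + gene_map["end"].to_numpy()) / 2.0
    chrom_arr = gene_map["chrom"].to_numpy()

    def event_shift(sub: int, role: str) -> np.ndarray:
        shift = np.zeros(n)
        for e in events:
            if e.subgroup is not None and e.subgroup != sub:
                continue
            if e.stage != "both" and e.stage != role:
                continue
            m = (chrom_arr == e.chrom) & (mid >= e.start) & (mid < e.end)
            shift[m] += spec.cna_attenuation * e.log2_ratio
        return shift

    def subgroup_shift(esub: int) -> np.ndarray:
        shift = np.zeros(n)
        b = spec.n_subgroup_genes
        shift[esub * b : (esub + 1) * b] += spec.expr_subgroup_effect
        return shift

    def subtype_shift(cls: str, gcimp: bool) -> np.ndarray:
        shift = np.zeros(n)
        idx, w = sig_weights[cls]
        shift[idx] += w
        gidx, gw = sig_weights["G-CIMP"]
        shift[gidx] += gw if gcimp else -gw
        return shift

    sample_rows = []
    mean_cols: dict[str, np.ndarray] = {}
    expr_cols: dict[str, np.ndarray] = {}
    seg_rows = []
    sample_index = 0

    for p in range(n_pat):
        pat = patients.iloc[p]
        prng = _rng(spec.seed, _S_NOISE, sample_index)
        pair_effect = prng.normal(0.0, spec.within_pair_sd, size=n)
        patient_events = [
            e for e in events
            if e.subgroup is None or e.subgroup == int(subgroup[p])
        ]
        pair_seg_noise = prng.normal(
            0.0, spec.cn_noise_sd, size=_segment_count(spec, patient_events)
        ).tolist()
        sample_index += 1
        for role, grade, cls in (
            ("initial", pat["initial_grade"], initial_subtype[p]),
            ("recurrent", pat["recurrent_grade"], recurrent_subtype[p]),
        ):
            sid = f"{pat['patient']}-{grade}{'i' if role == 'initial' else 'r'}"
            mean = (
                baseline
                + event_shift(int(subgroup[p]), role)
                + subgroup_shift(int(expr_subgroup[p]))
                + subtype_shift(cls, gcimp_positive[p])
                + pair_effect
            )
            noise = _rng(spec.seed, _S_NOISE, sample_index).normal(
                0.0, spec.noise_sd, size=n
            )
            mean_cols[sid] = mean
            expr_cols[sid] = mean + noise
            # copy-number segments: patient-shared segmentation and noise
            carried = [
                e for e in patient_events
                if e.stage == "both" or e.stage == role
            ]
            srng = _rng(spec.seed, _S_SEG, sample_index)
            for chrom, lo, hi, val in _sample_segments(
                spec, patient_events, carried, pair_seg_noise, srng
            ):
                seg_rows.append((sid, chrom, lo, hi, val))
            sample_rows.append(
                (
                    sid,
                    pat["patient"],
                    role,
                    grade,
                    pat["group"],
                    int(subgroup[p]),
                    int(expr_subgroup[p]),
                    cls,
                    bool(gcimp_positive[p]),
                )
            )
            sample_index += 1

    for j in range(spec.n_normals):
        sid = f"N{j + 1:02d}"
        noise = _rng(spec.seed, _S_NOISE, sample_index).normal(
            0.0, spec.noise_sd, size=n
        )
        mean_cols[sid] = baseline.copy()
        expr_cols[sid] = baseline + noise
        sample_rows.append((sid, "", "normal", "NB", "", -1, -1, "", False))
        sample_index += 1

    logexpr = pd.DataFrame(expr_cols, index=genes)
    expr_mean = pd.DataFrame(mean_cols, index=genes)
    sample_sheet = pd.DataFrame(
        sample_rows,
        columns=[
            "sample", "patient", "role", "grade", "group",
            "subgroup", "expr_subgroup", "subtype", "gcimp",
        ],
    )
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "seg_mean"]
    )

    # integer counts consistent with the log2 expression (Poisson sampling)
    counts_cols = {}
    for j, sid in enumerate(logexpr.columns):
        lam = 2.0 ** logexpr[sid].to_numpy() * spec.library_size / 1e6
        counts_cols[sid] = _rng(spec.seed, _S_COUNTS, j).poisson(lam)
    counts = pd.DataFrame(counts_cols, index=genes)

    truth = SimTruth(
        subgroup=sample_sheet.set_index("sample")["subgroup"],
        expr_subgroup=sample_sheet.set_index("sample")["expr_subgroup"],
        subtype=sample_sheet.set_index("sample")["subtype"],
        gcimp=sample_sheet.set_index("sample")["gcimp"],
        expr_mean=expr_mean,
    )
    return SimulatedCohort(
        gene_map, logexpr, counts, segments, sample_sheet, signatures, truth
    )


def pairs_table(sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """(patient, initial, recurrent) sample-id triples from a sample sheet."""
    tumors = sample_sheet[sample_sheet["role"].isin(["initial", "recurrent"])]
    rows = []
    for patient, grp in tumors.groupby("patient", sort=False):
        ini = grp.loc[grp["role"] == "initial", "sample"]
        rec = grp.loc[grp["role"] == "recurrent", "sample"]
        if len(ini) == 1 and len(rec) == 1:
            rows.append((patient, ini.iloc[0], rec.iloc[0]))
    return pd.DataFrame(rows, columns=["patient", "initial", "recurrent"])


# ---------------------------------------------------------------------------
# HMM pair profiles
# ---------------------------------------------------------------------------

def simulate_pair_profiles(
    spec: CohortSpec, gene_map: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-pair log-ratio profiles sampled from the planted HMM.

    Each chromosome restarts from the initial distribution; hidden states
    follow the Markov chain and observations the state-specific normals.
    Returns (genes x patients profiles, truth with genes x patients states).
    """
    spec.validate()
    if gene_map is None:
        gene_map = build_gene_map(spec)
    params = spec.hmm_truth
    patients = _patient_table(spec)["patient"].tolist()
    chrom = gene_map["chrom"].to_numpy()
    chrom_sizes = [int((chrom == c).sum()) for c in dict.fromkeys(chrom)]
    profiles = {}
    states = {}
    for i, pat in enumerate(patients):
        rng = _rng(spec.seed, _S_HMM, i)
        path = []
        for size in chrom_sizes:
            s = rng.choice(params.n_states, p=params.startprob)
            path.append(s)
            for _ in range(size - 1):
                s = rng.choice(params.n_states, p=params.transmat[s])
                path.append(s)
        path = np.asarray(path)
        obs = rng.normal(params.means[path], np.sqrt(params.variances[path]))
        profiles[pat] = obs
        states[pat] = path - 1  # codes -1/0/+1
    genes = gene_map["gene"].to_numpy()
    return (
        pd.DataFrame(profiles, index=genes),
        SimTruth(hmm_states=pd.DataFrame(states, index=genes)),
    )


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def synthetic_annotations(
    gene_map: pd.DataFrame,
    n_pathways: int = 8,
    pathway_size: int = 60,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene-category annotation sets for enrichment stages.

    Emits the cancer-relevant category vocabulary (EG, OG, TS, CC, PO, KI,
    MG, SG, TF) plus ``n_pathways`` synthetic signaling-pathway sets, each a
    seeded random draw from the gene universe.
    """
    rng = _rng(seed, _S_CENTROID, 999)
    genes = gene_map["gene"].to_numpy()
    out: dict[str, set[str]] = {}
    for cat in ("EG", "OG", "TS", "CC", "PO", "KI", "MG", "SG", "TF"):
        size = max(5, int(0.05 * genes.size))
        out[cat] = set(rng.choice(genes, size=size, replace=False))
    for i in range(n_pathways):
        out[f"pathway_{i + 1:02d}"] = set(
            rng.choice(genes, size=min(pathway_size, genes.size), replace=False)
        )
    return out


def default_mutated_gene_truth(gene_map: pd.DataFrame) -> dict[str, float]:
    """Recurrently mutated marker genes: first gene of chr1/chr2/chr3 with
    pair fractions echoing the IDH1-like / TP53-like / MUC4-like pattern."""
    firsts = gene_map.groupby("chrom", sort=False).head(1).set_index("chrom")["gene"]
    fractions = [12 / 17, 10 / 17, 6 / 17]
    out = {}
    for i, frac in enumerate(fractions):
        chrom = f"chr{i + 1}"
        if chrom in firsts.index:
            out[firsts[chrom]] = frac
    return out


def simulate_variant_tables(
    spec: CohortSpec, gene_map: pd.DataFrame | None = None
) -> tuple[dict[str, tuple[pd.DataFrame, pd.DataFrame]], SimTruth]:
    """Paired somatic variant call sets with planted shared/private counts.

    Returns (patient -> (initial calls, recurrent calls), truth). Counts per
    pair come from ``spec.variant_truth`` when given, else Poisson draws
    around ``spec.variant_means``. Recurrently mutated marker genes carry a
    shared variant at one fixed position in the planted fraction of pairs.
    """
    spec.validate()
    if gene_map is None:
        gene_map = build_gene_map(spec)
    patients = _patient_table(spec)["patient"].tolist()
    gene_truth = (
        spec.mutated_gene_truth
        if spec.mutated_gene_truth is not None
        else default_mutated_gene_truth(gene_map)
    )
    gmap = gene_map.set_index("gene")
    classes = list(FUNC_CLASS_PROBS)
    probs = np.asarray(list(FUNC_CLASS_PROBS.values()))
    bases = np.array(["A", "C", "G", "T"])

    pair_sets: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    counts_truth: dict[str, tuple[int, int, int]] = {}
    keys_truth: dict[str, dict[str, set]] = {}

    for i, pat in enumerate(patients):
        rng = _rng(spec.seed, _S_VARIANT, i)
        if spec.variant_truth is not None and pat in spec.variant_truth:
            n_shared, n_ip, n_rp = spec.variant_truth[pat]
        elif spec.variant_truth is not None:
            n_shared, n_ip, n_rp = 0, 0, 0
        else:
            n_shared, n_ip, n_rp = (
                int(rng.poisson(m)) for m in spec.variant_means
            )
        total = n_shared + n_ip + n_rp
        # draw distinct variant keys: gene + offset within the gene
        gidx = rng.integers(0, len(gmap), size=total)
        made: set[tuple] = set()
        variants = []
        planted = [
            g for g, frac in gene_truth.items()
            if i < round(frac * len(patients))
        ]
        for j in range(total):
            if j < len(planted) and j < n_shared:
                g = planted[j]
                pos = int(gmap.loc[g, "start"]) + 100
            else:
                g = gmap.index[gidx[j]]
                pos = int(gmap.loc[g, "start"]) + int(
                    rng.integers(0, max(1, gmap.loc[g, "end"] - gmap.loc[g, "start"]))
                )
            chrom = gmap.loc[g, "chrom"]
            ref, alt = rng.choice(bases, size=2, replace=False)
            key = (chrom, pos, ref, alt)
            while key in made:
                pos += 1
                key = (chrom, pos, ref, alt)
            made.add(key)
            variants.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": g,
                    "func_class": rng.choice(classes, p=probs),
                    "vaf": float(np.round(rng.uniform(0.05, 0.9), 3)),
                }
            )
        shared = variants[:n_shared]
        ipriv = variants[n_shared : n_shared + n_ip]
        rpriv = variants[n_shared + n_ip :]
        cols = ["chrom", "pos", "ref", "alt", "gene", "func_class", "vaf"]
        initial = pd.DataFrame(shared + ipriv, columns=cols)
        recurrent = pd.DataFrame(shared + rpriv, columns=cols)
        initial.insert(0, "sample", f"{pat}-initial")
        recurrent.insert(0, "sample", f"{pat}-recurrent")
        pair_sets[pat] = (initial, recurrent)
        counts_truth[pat] = (n_shared, n_ip, n_rp)
        keyof = lambda v: (v["chrom"], v["pos"], v["ref"], v["alt"])
        keys_truth[pat] = {
            "shared": {keyof(v) for v in shared},
            "initial_private": {keyof(v) for v in ipriv},
            "recurrent_private": {keyof(v) for v in rpriv},
        }

    truth = SimTruth(
        variant_counts=counts_truth,
        variant_keys=keys_truth,
        mutated_gene_truth=dict(gene_truth),
    )
    return pair_sets, truth
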