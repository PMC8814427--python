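"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the statistical structure the aneuploidy analysis assumes for a
tumor cohort with matched normals:

* segmented absolute copy-number profiles with planted whole-arm
  amplifications/deletions relative to each sample's ploidy, plus
  per-sample purity/ploidy (ABSOLUTE-style output) and a leukocyte
  fraction;
* a promoter-methylation layer in which planted driver genes gain beta
  value linearly with the sample's aneuploidy score (AS), with a 450K-style
  probe manifest containing in-window and out-of-window probes and
  SNP/multi-hit/sex-chromosome probes to exercise the filters;
* an RNA-seq counts layer in which planted drivers are down-regulated in
  tumors and additionally repressed by their own promoter methylation, and
  a co-expressed "proliferation module" rises with AS;
* a mutation layer with one TP53-like gene whose mutation probability is
  logistic in AS over a flat background;
* a clinical table with AS-dependent progression hazard and AS-coupled
  stage/grade labels.

Every stochastic quantity is drawn from a generator keyed on the mandatory
seed, so a fixed seed fixes every byte of output.  The returned
:class:`SimTruth` records exactly what was planted, for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .arm_scoring import GenomeModel, SegmentProfile, default_genome, round_half_up


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a mid-size primary-tumor cohort: ~10% of arms
    altered per sample (median AS around 4 of 44 arms), mostly diploid
    genomes, purity around 0.73, and 15 hyper-methylated/down-expressed
    driver genes among 2,000.
    """

    seed: int
    n_tumor: int = 200
    n_normal: int = 50
    genome: GenomeModel = field(default_factory=default_genome)

    # copy-number layer
    arm_event_prob: float = 0.1
    amp_fraction: float = 0.5          # amplified share of planted events
    event_magnitude: int = 1           # copies added/removed per event
    ploidy_weights: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.85, 3: 0.10, 4: 0.05})
    ploidy_jitter: float = 0.3         # uniform jitter, keeps round() intact
    purity_beta: tuple[float, float] = (8.0, 3.0)
    frag_rate: float = 1.0             # mean extra breakpoints per arm
    centromere_span_frac: float = 0.3  # chance of merging across centromere

    # gene universe and methylation layer
    n_genes: int = 2000
    n_driver: int = 15
    driver_meth_slope: float = 0.01    # beta units per AS unit
    driver_beta_baseline: float = 0.10
    meth_noise_sd: float = 0.02
    probe_noise_sd: float = 0.01
    probes_in_window: int = 2
    tss_window_bp: int = 1000
    n_flagged_probes: int = 30         # each of SNP / multi-hit / allosome

    # expression layer
    driver_lfc: float = -1.0           # log2 tumor-vs-normal for drivers
    expr_meth_coupling: float = -15.0  # log2 units per beta unit
    expr_dispersion: float = 0.02
    n_module_genes: int = 50
    module_lfc_per_as: float = 0.1     # log2 units per AS unit
    library_size_sd: float = 0.15      # log-normal sd of sample depth

    # mutation layer
    tp53_base_logit: float = -3.0
    tp53_as_slope: float = 0.3
    background_mut_low: float = 0.005
    background_mut_high: float = 0.05

    # clinical layer
    hazard_log_hr_per_as: float = 0.05     # per AS unit, PFI
    baseline_hazard: float = 5e-4          # events/day at AS = 0
    censor_rate: float = 5e-4              # independent censoring, per day
    admin_censor_days: float = 3650.0
    dfs_baseline_hazard: float = 3e-4
    short_survival_frac: float = 0.02      # samples with time <= 30 days
    age_mean: float = 61.0
    age_sd: float = 7.0
    age_as_slope: float = 0.0
    stage_as_slope: float = 0.3            # ordered-logit slope, all labels

    # confounding switch: leukocyte fraction coupled to AS, and null-gene
    # methylation coupled to leukocyte fraction (tests covariate adjustment)
    confounded_leukocyte: bool = False
    leukocyte_as_slope: float = 0.03
    meth_leukocyte_coeff: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if not (0.0 <= self.arm_event_prob <= 1.0):
            raise ValueError("arm_event_prob must lie in [0, 1]")
        if not (0.0 <= self.amp_fraction <= 1.0):
            raise ValueError("amp_fraction must lie in [0, 1]")
        if self.n_driver + self.n_module_genes > self.n_genes:
            raise ValueError("n_driver + n_module_genes exceeds n_genes")
        for name in ("short_survival_frac", "centromere_span_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed generator so stages are independently reproducible."""
        return np.random.default_rng([int(stage), int(self.seed)])


@dataclass
class SimTruth:
    """What was planted: the oracle against which recovery is measured."""

    arm_events: pd.DataFrame            # tumor samples x arms, in {-1, 0, +1}
    true_as: pd.Series                  # per tumor sample
    ploidy: pd.Series
    purity: pd.Series
    leukocyte: pd.Series
    tumor_samples: list[str]
    normal_samples: list[str]
    genes: list[str] = field(default_factory=list)
    driver_genes: list[str] = field(default_factory=list)
    module_genes: list[str] = field(default_factory=list)
    tp53_gene: str = "TP53"
    gene_info: pd.DataFrame | None = None   # gene, chrom, pos, arm
    hazard_log_hr_per_as: float = float("nan")

    def __post_init__(self) -> None:
        expected = (self.arm_events != 0).sum(axis=1)
        if not expected.equals(self.true_as.astype(expected.dtype)):
            raise ValueError("true_as must equal the planted event count")


# ---------------------------------------------------------------------------
# copy-number cohort
# ---------------------------------------------------------------------------

def _arm_segments(rng, start: int, end: int, cn: int, frag_rate: float):
    """Cover [start, end] with 1 + Poisson(frag_rate) segments of copy cn."""
    n_break = int(rng.poisson(frag_rate))
    n_break = min(n_break, end - start)  # need room for distinct breakpoints
    cuts = np.array([], dtype=np.int64)
    while len(cuts) < n_break:  # arms are huge, so collisions are ~never
        draw = rng.integers(start, end, size=n_break - len(cuts))
        cuts = np.unique(np.concatenate([cuts, draw]))
    cuts.sort()
    bounds = np.concatenate(([start - 1], cuts, [end]))
    return [(int(bounds[i] + 1), int(bounds[i + 1]), cn)
            for i in range(len(bounds) - 1)]


def gen_cohort(config: SimConfig):
    """Generate segmented profiles, a purity/ploidy/leukocyte table and truth.

    Arms drawn for an event have every overlapping segment shifted by
    ``event_magnitude`` copies from the rounded sample ploidy; neutral arms
    sit exactly at the rounded ploidy.  A fraction of adjacent p/q segments
    with equal copy number is merged across the centromere so that
    centromere splitting is exercised downstream.
    """
    rng = config.rng(1)
    genome = config.genome
    arms = genome.arms
    arm_names = [a.name for a in arms]
    samples = [f"T{i + 1:04d}" for i in range(config.n_tumor)]
    normals = [f"N{i + 1:04d}" for i in range(config.n_normal)]

    ploidy_levels = np.array(sorted(config.ploidy_weights))
    ploidy_p = np.array([config.ploidy_weights[k] for k in ploidy_levels],
                        dtype=float)
    ploidy_p /= ploidy_p.sum()

    events = pd.DataFrame(0, index=samples, columns=arm_names, dtype=int)
    profiles: list[SegmentProfile] = []
    ploidies, purities = {}, {}

    for s in samples:
        base = int(rng.choice(ploidy_levels, p=ploidy_p))
        ploidy = base + float(rng.uniform(-config.ploidy_jitter,
                                          config.ploidy_jitter))
        purity = float(rng.beta(*config.purity_beta))
        ploidies[s], purities[s] = ploidy, purity

        has_event = rng.random(len(arms)) < config.arm_event_prob
        sign = np.where(rng.random(len(arms)) < config.amp_fraction, 1, -1)
        ev = np.where(has_event, sign, 0)
        events.loc[s] = ev

        neutral_cn = round_half_up(ploidy)
        rows = []
        for chrom, (length, cen) in genome.chromosomes.items():
            cn_by_arm = {}
            arm_segs = {}
            for arm_name, a_start, a_end in (
                    (f"{chrom}p", 1, cen), (f"{chrom}q", cen + 1, length)):
                e = ev[arm_names.index(arm_name)]
                cn = max(neutral_cn + int(e) * config.event_magnitude, 0)
                cn_by_arm[arm_name] = cn
                arm_segs[arm_name] = _arm_segments(rng, a_start, a_end, cn,
                                                   config.frag_rate)
            p_segs, q_segs = arm_segs[f"{chrom}p"], arm_segs[f"{chrom}q"]
            if (cn_by_arm[f"{chrom}p"] == cn_by_arm[f"{chrom}q"]
                    and rng.random() < config.centromere_span_frac):
                # merge the flanking segments into one centromere-spanning one
                left, right = p_segs[-1], q_segs[0]
                p_segs = p_segs[:-1] + [(left[0], right[1], left[2])]
                q_segs = q_segs[1:]
            for st, en, cn in p_segs + q_segs:
                rows.append((chrom, st, en, cn))
        seg = pd.DataFrame(rows,
                           columns=["chromosome", "start", "end",
                                    "copy_number"])
        profiles.append(SegmentProfile(sample=s, segments=seg,
                                       purity=purity, ploidy=ploidy))

    true_as = (events != 0).sum(axis=1)
    ploidy_s = pd.Series(ploidies, name="ploidy")
    purity_s = pd.Series(purities, name="purity")

    stroma = 1.0 - purity_s
    if config.confounded_leukocyte:
        centered = true_as - float(true_as.mean())
        raw = 0.1 + config.leukocyte_as_slope * centered \
            + rng.normal(0.0, 0.02, size=len(samples))
        leuk = pd.Series(np.clip(raw, 0.0, stroma.to_numpy()), index=samples)
    else:
        leuk = pd.Series(
            stroma.to_numpy() * rng.beta(2.0, 5.0, size=len(samples)),
            index=samples)
    leuk.name = "leukocyte"

    pp = pd.DataFrame({"purity": purity_s, "ploidy": ploidy_s,
                       "leukocyte": leuk})
    pp.index.name = "sample"

    truth = SimTruth(
        arm_events=events, true_as=true_as,
        ploidy=ploidy_s, purity=purity_s, leukocyte=leuk,
        tumor_samples=samples, normal_samples=normals,
        hazard_log_hr_per_as=config.hazard_log_hr_per_as,
    )
    return profiles, pp, truth


# ---------------------------------------------------------------------------
# omics layers
# ---------------------------------------------------------------------------

@dataclass
class OmicsBundle:
    """The generated omics matrices, in the shapes the pipeline reads."""

    mutation: pd.DataFrame      # genes x tumor samples, binary
    beta: pd.DataFrame          # probes x (tumor + normal) samples, in [0,1]
    manifest: pd.DataFrame      # probe_id, chrom, pos, gene, tss_distance_bp,
                                # snp_flag, multihit_flag
    counts: pd.DataFrame        # genes x (tumor + normal) samples, ints
    gene_cna: pd.DataFrame      # genes x tumor samples, in {-1, 0, +1}


def gen_omics(truth: SimTruth, config: SimConfig) -> OmicsBundle:
    """Generate mutation, methylation (+manifest) and expression layers.

    Planted drivers: tumor promoter beta = baseline + slope * AS + noise
    (truncated to [0, 1]); expression negative-binomial with the tumor mean
    scaled by 2**driver_lfc and further reduced as the gene's own
    methylation rises.  Module genes rise log-linearly with AS.  All other
    genes are exchangeable between tumors and normals.
    """
    rng = config.rng(2)
    genome = config.genome
    tumors, normals = truth.tumor_samples, truth.normal_samples
    all_samples = tumors + normals
    as_t = truth.true_as.loc[tumors].to_numpy(dtype=float)

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    genes[0] = "TP53"
    special = rng.choice(
        np.arange(1, config.n_genes),
        size=config.n_driver + config.n_module_genes, replace=False)
    drivers = [genes[i] for i in special[:config.n_driver]]
    module = [genes[i] for i in special[config.n_driver:]]

    # gene coordinates, chromosome chosen proportional to its length
    chroms = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c][0] for c in chroms], float)
    gi_chrom = rng.choice(chroms, size=config.n_genes, p=lengths / lengths.sum())
    gi_pos = np.array([
        int(rng.integers(1, genome.chromosomes[c][0] + 1)) for c in gi_chrom])
    gene_info = pd.DataFrame({
        "gene": genes, "chrom": gi_chrom, "pos": gi_pos,
        "arm": [genome.arm_of(c, p) for c, p in zip(gi_chrom, gi_pos)],
    }).set_index("gene")

    truth.genes = genes
    truth.driver_genes = drivers
    truth.module_genes = module
    truth.tp53_gene = "TP53"
    truth.gene_info = gene_info

    # --- mutation layer (tumors only) ------------------------------------
    bg = rng.uniform(config.background_mut_low, config.background_mut_high,
                     size=config.n_genes)
    prob = np.tile(bg[:, None], (1, len(tumors)))
    prob[genes.index("TP53"), :] = _sigmoid(
        config.tp53_base_logit + config.tp53_as_slope * as_t)
    mutation = pd.DataFrame(
        (rng.random(prob.shape) < prob).astype(int),
        index=pd.Index(genes, name="gene"), columns=tumors)

    # --- methylation layer ------------------------------------------------
    baseline = rng.uniform(0.15, 0.60, size=config.n_genes)
    is_driver = np.isin(genes, drivers)
    baseline[is_driver] = config.driver_beta_baseline

    signal = np.tile(baseline[:, None], (1, len(all_samples)))
    driver_rows = np.flatnonzero(is_driver)
    signal[np.ix_(driver_rows, np.arange(len(tumors)))] += \
        config.driver_meth_slope * as_t[None, :]
    if config.confounded_leukocyte and config.meth_leukocyte_coeff:
        leuk_t = truth.leukocyte.loc[tumors].to_numpy()
        signal[:, :len(tumors)] += config.meth_leukocyte_coeff * (
            leuk_t[None, :] - float(truth.leukocyte.mean()))
    gene_beta = np.clip(
        signal + rng.normal(0.0, config.meth_noise_sd, size=signal.shape),
        0.0, 1.0)

    probe_rows, probe_betas = [], []
    k = 0
    for gi, g in enumerate(genes):
        c, p = gene_info.loc[g, "chrom"], int(gene_info.loc[g, "pos"])
        for _ in range(config.probes_in_window):
            d = int(rng.integers(-config.tss_window_bp,
                                 config.tss_window_bp + 1))
            probe_rows.append((f"cg{k:07d}", c, p + d, g, d, 0, 0))
            probe_betas.append(gene_beta[gi])
            k += 1
        d = int(rng.integers(1500, 50001)) * (1 if rng.random() < 0.5 else -1)
        probe_rows.append((f"cg{k:07d}", c, p + d, g, d, 0, 0))
        probe_betas.append(np.full(len(all_samples),
                                   float(rng.uniform(0.2, 0.8))))
        k += 1
    # probes the filters must remove: SNP-flagged, multi-hit, allosome
    for flag_kind in ("snp", "multihit", "allosome"):
        for _ in range(config.n_flagged_probes):
            g = genes[int(rng.integers(config.n_genes))]
            c = gene_info.loc[g, "chrom"]
            d = int(rng.integers(-config.tss_window_bp,
                                 config.tss_window_bp + 1))
            snp = int(flag_kind == "snp")
            multi = int(flag_kind == "multihit")
            if flag_kind == "allosome":
                c = "X" if rng.random() < 0.5 else "Y"
            probe_rows.append(
                (f"cg{k:07d}", c, int(gene_info.loc[g, "pos"]) + d, g, d,
                 snp, multi))
            # extreme values so un-filtered use would distort gene means
            probe_betas.append(np.full(len(all_samples),
                                       float(rng.choice([0.0, 1.0]))))
            k += 1

    manifest = pd.DataFrame(
        probe_rows,
        columns=["probe_id", "chrom", "pos", "gene", "tss_distance_bp",
                 "snp_flag", "multihit_flag"]).set_index("probe_id")
    beta_arr = np.clip(
        np.vstack(probe_betas)
        + rng.normal(0.0, config.probe_noise_sd,
                     size=(len(probe_rows), len(all_samples))),
        0.0, 1.0)
    beta = pd.DataFrame(beta_arr, index=manifest.index, columns=all_samples)

    # --- expression layer -------------------------------------------------
    base_mean = rng.lognormal(mean=np.log(300.0), sigma=1.0,
                              size=config.n_genes)
    log2_mu = np.tile(np.log2(base_mean)[:, None], (1, len(all_samples)))
    t_idx = np.arange(len(tumors))
    log2_mu[np.ix_(driver_rows, t_idx)] += config.driver_lfc \
        + config.expr_meth_coupling * (
            gene_beta[np.ix_(driver_rows, t_idx)] - baseline[driver_rows, None])
    module_rows = np.flatnonzero(np.isin(genes, module))
    log2_mu[np.ix_(module_rows, t_idx)] += \
        config.module_lfc_per_as * as_t[None, :]

    lib = rng.lognormal(mean=0.0, sigma=config.library_size_sd,
                        size=len(all_samples))
    mu = np.maximum(2.0 ** log2_mu * lib[None, :], 1e-8)
    r = 1.0 / config.expr_dispersion
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + mu)).astype(int),
        index=pd.Index(genes, name="gene"), columns=all_samples)

    # --- gene-level CNA calls (tumors only), inherited from the arm -------
    gene_cna = truth.arm_events.T.reindex(gene_info["arm"]).to_numpy()
    gene_cna = pd.DataFrame(gene_cna, index=pd.Index(genes, name="gene"),
                            columns=tumors)

    return OmicsBundle(mutation=mutation, beta=beta, manifest=manifest,
                       counts=counts, gene_cna=gene_cna)


# ---------------------------------------------------------------------------
# clinical layer
# ---------------------------------------------------------------------------

def _ordered_logit(rng, latent: np.ndarray, cutpoints, labels):
    """Draw ordinal labels from an ordered-logit model."""
    u = latent + rng.logistic(0.0, 1.0, size=latent.shape)
    idx = np.searchsorted(np.asarray(cutpoints, float), u, side="right")
    return np.asarray(labels, dtype=object)[idx]


def gen_clinical(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Clinical table: AS-dependent progression hazard and stage labels.

    PFI/DFS times are exponential with log-hazard linear in AS, censored
    independently and administratively; T/N/M stage and Gleason pattern
    scores follow ordered-logit models whose latent scale rises with AS.
    A ``short_survival_frac`` share of samples is given a time of at most
    30 days to exercise the cohort filter.
    """
    rng = config.rng(3)
    samples = truth.tumor_samples
    n = len(samples)
    as_t = truth.true_as.loc[samples].to_numpy(dtype=float)

    def survival(base_rate):
        rate = base_rate * np.exp(config.hazard_log_hr_per_as * as_t)
        t_event = rng.exponential(1.0 / rate)
        t_cens = np.minimum(rng.exponential(1.0 / config.censor_rate, size=n),
                            config.admin_censor_days)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return np.ceil(time), event

    pfi_time, pfi_event = survival(config.baseline_hazard)
    dfs_time, dfs_event = survival(config.dfs_baseline_hazard)

    short = rng.random(n) < config.short_survival_frac
    if short.any():
        pfi_time[short] = rng.integers(1, 31, size=int(short.sum()))
        pfi_event[short] = rng.integers(0, 2, size=int(short.sum()))

    age = rng.normal(config.age_mean, config.age_sd, size=n) \
        + config.age_as_slope * as_t

    s = config.stage_as_slope
    latent = s * as_t
    anchor = s * float(np.mean(as_t))
    # cutpoints anchored so that marginal label frequencies at the mean AS
    # resemble a localized prostate-cancer cohort
    t_stage = _ordered_logit(rng, latent, anchor + np.array([-5.5, -0.43, 3.9]),
                             ["T1", "T2", "T3", "T4"])
    n_stage = np.where(
        rng.random(n) < _sigmoid(-2.8 + s * as_t), "N1", "N0")
    m_stage = np.where(
        rng.random(n) < _sigmoid(-5.7 + 0.1 * as_t), "M1", "M0")
    gleason_primary = _ordered_logit(
        rng, latent, anchor + np.array([-0.36, 2.4]), [3, 4, 5])
    gleason_secondary = _ordered_logit(
        rng, latent, anchor + np.array([-0.80, 1.22]), [3, 4, 5])

    clin = pd.DataFrame({
        "sample": samples,
        "pfi_time": pfi_time.astype(int),
        "pfi_event": pfi_event.astype(int),
        "dfs_time": dfs_time.astype(int),
        "dfs_event": dfs_event.astype(int),
        "age": np.round(age, 1),
        "t_stage": t_stage,
        "n_stage": n_stage,
        "m_stage": m_stage,
        "gleason_primary": gleason_primary.astype(int),
        "gleason_secondary": gleason_secondary.astype(int),
    }).set_index("sample")
    return clin


def gen_gene_sets(truth: SimTruth, config: SimConfig,
                  n_random_sets: int = 20, set_size: int = 30
                  ) -> dict[str, list[str]]:
    """Gene sets for enrichment stages: the planted co-expression module
    (a cell-cycle stand-in) plus random sets drawn from the gene universe."""
    rng = config.rng(4)
    sets = {"PLANTED_CELL_CYCLE_MODULE": list(truth.module_genes)}
    for i in range(n_random_sets):
        members = rng.choice(truth.genes, size=set_size, replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(members)
    return sets
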