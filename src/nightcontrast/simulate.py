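"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (SNP calling, differential
expression, presence-absence calling, qPCR quantification, metabolite
heterosis statistics) can be exercised on data from this module without
any external download.  The generators emulate the statistical structure
of a two-accession comparison between substantially inbred lines: the
two genomes diverge at ~1 SNP per 10 kb of transcript, a 454-scale
library of ~60 reads per gene is split between the accessions, ~18.5% of
expressed genes show presence-absence variation, and the metabolome of
the F1 hybrid mixes additive, dominant, and transgressive modes.

All randomness flows from a single integer seed.  Each output file gets
its own derived generator stream so that, e.g., the metabolite table can
be regenerated without re-simulating the pileups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# fixed stream ids so each output can be regenerated independently
_STREAM_PILEUP = 11
_STREAM_COUNTS = 12
_STREAM_METAB = 13
_STREAM_QPCR = 14

HETEROSIS_MODES = ("additive", "dominant", "transgressive_up", "transgressive_down")
ARTIFACT_CLASSES = ("heterozygous", "low_fraction", "cluster", "reference_discordant")


@dataclass
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults encode the conditions of the two-accession dark-period
    study: SNP density 1e-4/bp, 18.5% PAV, ~62 uniquely aligned reads
    per gene (>1 M reads over ~18k genes), n=4 replicates in metabolite
    experiment 1 and n=3 in experiment 2, and a fivefold qPCR dilution
    gradient.
    """

    seed: int = 0
    # --- pileups / SNPs ---
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (500, 1500)
    snp_rate: float = 1e-4
    error_rate: float = 0.005          # 454-era substitution miscall rate
    het_artifact_rate: float = 2e-4    # per-site artifactual heterozygosity
    lowfrac_artifact_rate: float = 2e-4
    refdisc_artifact_rate: float = 2e-4
    cluster_artifact_rate: float = 0.02  # per-gene planted >=5-SNP/100-bp cluster
    depth_mean: float = 20.0
    mapq: int = 60
    # --- count table ---
    pav_fraction: float = 0.185
    de_fraction: float = 31 / 17888
    fold_range: tuple[float, float] = (2.0, 8.0)  # |log2 fold| of planted DEGs
    mean_expression: float = 62.0       # reads per gene per accession
    expression_sigma: float = 1.5       # sd of log gene baseline
    # the table holds *detected* genes, so baselines sit above a detection
    # floor; without it, sampling zeros masquerade as presence-absence
    min_expression: float = 5.0
    dispersion: float = 0.05            # NB dispersion alpha
    # --- metabolome ---
    n_metabolites: int = 144
    metab_n1: int = 4
    metab_n2: int = 3
    heterosis_mix: tuple[float, float, float, float] = (0.58, 0.25, 0.03, 0.14)
    transgressive_margin: float = 0.5
    parental_ratio_range: tuple[float, float] = (2.0, 4.0)
    parent_absent_fraction: float = 4 / 144
    cv_metab: float = 0.1
    exp_shift_sigma: float = 0.3
    # --- qPCR ---
    qpcr_slope: float = -3.3219
    qpcr_intercept: float = 22.0
    qpcr_sd: float = 0.2
    qpcr_tech_reps: int = 3
    qpcr_n_targets: int = 3

    def validate(self) -> None:
        rates = {
            "snp_rate": self.snp_rate,
            "error_rate": self.error_rate,
            "het_artifact_rate": self.het_artifact_rate,
            "lowfrac_artifact_rate": self.lowfrac_artifact_rate,
            "refdisc_artifact_rate": self.refdisc_artifact_rate,
            "cluster_artifact_rate": self.cluster_artifact_rate,
            "pav_fraction": self.pav_fraction,
            "de_fraction": self.de_fraction,
            "parent_absent_fraction": self.parent_absent_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_metabolites <= 0:
            raise ValueError("n_metabolites must be positive")
        if len(self.heterosis_mix) != 4:
            raise ValueError("heterosis_mix must have 4 entries")
        if any(p < 0 for p in self.heterosis_mix):
            raise ValueError("heterosis_mix entries must be >= 0")
        if abs(sum(self.heterosis_mix) - 1.0) > 1e-9:
            raise ValueError("heterosis_mix must sum to 1")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid gene_length_range")
        if self.metab_n1 < 2 or self.metab_n2 < 2:
            raise ValueError("metabolite replicate counts must be >= 2")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Exhaustive record of every planted feature.

    Downstream recall/precision can be computed from this object alone;
    no generator internals need to be consulted.
    """

    # (seq_id, pos, ref, alt) of clean accession-differentiating SNPs
    true_snps: list[tuple[str, int, str, str]] = field(default_factory=list)
    # (seq_id, pos, artifact_class, ref, alt); classes are disjoint per site
    artifact_sites: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    # gene -> "both" | "sh_only" | "yk_only"
    true_pav: dict[str, str] = field(default_factory=dict)
    # gene -> planted log2(YK/SH) fold (DE genes only)
    true_fold: dict[str, float] = field(default_factory=dict)
    # metabolite -> (mode, mean_SH, mean_YK, mean_F1)
    metab_class: dict[str, tuple[str, float, float, float]] = field(default_factory=dict)
    # metabolites with one parent forced to zero -> absent parent name
    metab_parent_absent: dict[str, str] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(1, n + 1)]


def _sample_base_counts(rng, true_base, depth, error_rate):
    """Per-site ACGT read counts: true base plus uniform miscalls.

    Miscalls are split among the three non-true bases by successive
    conditional binomials, which is equivalent to a multinomial draw but
    vectorizes over sites.
    """
    n = len(true_base)
    errs = rng.binomial(depth, error_rate)
    e1 = rng.binomial(errs, 1.0 / 3.0)
    e2 = rng.binomial(errs - e1, 0.5)
    e3 = errs - e1 - e2
    counts = np.zeros((n, 4), dtype=np.int64)
    idx = np.arange(n)
    counts[idx, true_base] = depth - errs
    counts[idx, (true_base + 1) % 4] += e1
    counts[idx, (true_base + 2) % 4] += e2
    counts[idx, (true_base + 3) % 4] += e3
    return counts


def simulate_pileups(config: SimConfig):
    """Paired per-site base-count pileups for the two accessions.

    Returns ``(reference, pileup_sh, pileup_yk, truth)`` where
    ``reference`` maps gene name to its sequence string and the pileups
    are DataFrames in the 9-column dialect (seq_id, pos, ref, A, C, G,
    T, depth, mapq; 1-based positions).

    Accession 1 (SH role) matches the reference everywhere except at
    planted reference-discordant artifacts; true SNPs appear as
    accession-2 (YK role) homozygous alternative sites.  Artifact
    classes (heterozygous, low-fraction, cluster, reference-discordant)
    are planted at their configured rates on sites disjoint from the
    true SNPs and from each other.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_PILEUP, config.seed])

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    names = _gene_names(config.n_genes)
    total = int(lengths.sum())
    gene_idx = np.repeat(np.arange(config.n_genes), lengths)
    pos = np.concatenate([np.arange(1, L + 1) for L in lengths])

    ref = rng.integers(0, 4, size=total)

    # site classes: 0 none, 1 snp, 2 het, 3 lowfrac, 4 refdisc, 5 cluster
    u = rng.random(total)
    edges = np.cumsum(
        [config.snp_rate, config.het_artifact_rate,
         config.lowfrac_artifact_rate, config.refdisc_artifact_rate]
    )
    site_class = np.zeros(total, dtype=np.int8)
    site_class[u < edges[3]] = 4
    site_class[u < edges[2]] = 3
    site_class[u < edges[1]] = 2
    site_class[u < edges[0]] = 1

    # planted SNP clusters: >=5 clean-looking SNPs inside one 100-bp window
    cluster_genes = np.flatnonzero(rng.random(config.n_genes) < config.cluster_artifact_rate)
    offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1]
    for g in cluster_genes:
        L = int(lengths[g])
        start = int(rng.integers(1, max(2, L - 99)))
        width = min(100, L - start + 1)
        picks = rng.choice(width, size=min(5, width), replace=False) + start
        flat = offsets[g] + picks - 1
        site_class[flat] = 5

    alt = (ref + rng.integers(1, 4, size=total)) % 4

    a1_true = ref.copy()
    a2_true = ref.copy()
    variant = np.isin(site_class, (1, 3, 5))
    a2_true[variant] = alt[variant]
    refdisc = site_class == 4
    a1_true[refdisc] = alt[refdisc]  # SH consensus disagrees with reference

    depth1 = rng.poisson(config.depth_mean, size=total)
    depth2 = rng.poisson(config.depth_mean, size=total)
    counts1 = _sample_base_counts(rng, a1_true, depth1, config.error_rate)
    counts2 = _sample_base_counts(rng, a2_true, depth2, config.error_rate)

    # heterozygous artifact: accession 2 carries a 55-70% alt / 30-45% ref mix
    het = np.flatnonzero(site_class == 2)
    if het.size:
        minor = rng.uniform(0.30, 0.45, size=het.size)
        d = depth2[het]
        alt_n = np.round(d * (1.0 - minor)).astype(np.int64)
        counts2[het] = 0
        counts2[het, alt[het]] = alt_n
        counts2[het, ref[het]] += d - alt_n
    # low-fraction artifact: two alt reads against one ref read in accession 2,
    # facing a deep (3x mean) reference-matching accession-1 site so the
    # pooled alt fraction stays well under the removal threshold
    low = np.flatnonzero(site_class == 3)
    if low.size:
        counts2[low] = 0
        counts2[low, alt[low]] = 2
        counts2[low, ref[low]] = 1
        depth2[low] = 3
        deep = rng.poisson(3.0 * config.depth_mean, size=low.size)
        counts1[low] = _sample_base_counts(
            rng, ref[low], deep, config.error_rate
        )
        depth1[low] = deep

    truth = GroundTruth()
    class_name = {2: "heterozygous", 3: "low_fraction", 4: "reference_discordant", 5: "cluster"}
    for flat in np.flatnonzero(site_class > 0):
        rec = (names[gene_idx[flat]], int(pos[flat]), BASES[ref[flat]], BASES[alt[flat]])
        if site_class[flat] == 1:
            truth.true_snps.append(rec)
        else:
            truth.artifact_sites.append(
                (rec[0], rec[1], class_name[int(site_class[flat])], rec[2], rec[3])
            )

    seq_ids = np.repeat(np.array(names, dtype=object), lengths)

    def frame(counts):
        return pd.DataFrame(
            {
                "seq_id": seq_ids,
                "pos": pos,
                "ref": BASES[ref],
                "A": counts[:, 0],
                "C": counts[:, 1],
                "G": counts[:, 2],
                "T": counts[:, 3],
                "depth": counts.sum(axis=1),
                "mapq": np.full(total, config.mapq, dtype=np.int64),
            }
        )

    reference = {}
    for g, name in enumerate(names):
        s, e = offsets[g], offsets[g] + lengths[g]
        reference[name] = "".join(BASES[ref[s:e]])

    return reference, frame(counts1), frame(counts2), truth


def simulate_counts(config: SimConfig):
    """Two-column gene read-count table with planted PAV and DEGs.

    Counts are negative binomial around lognormal baseline means whose
    expectation is ``mean_expression`` reads per gene, so the library
    totals track the ~1 M-read scale of the study when n_genes is at
    full scale.  PAV genes are structural zeros in one accession; DE
    genes carry the recorded log2(YK/SH) fold.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_COUNTS, config.seed])
    names = _gene_names(config.n_genes)
    sigma = config.expression_sigma
    mu = np.log(config.mean_expression) - sigma**2 / 2.0
    base = np.maximum(rng.lognormal(mu, sigma, size=config.n_genes), config.min_expression)

    truth = GroundTruth()
    u = rng.random(config.n_genes)
    is_pav = u < config.pav_fraction
    is_de = (~is_pav) & (u < config.pav_fraction + config.de_fraction)

    pav_side = rng.random(config.n_genes) < 0.5  # True -> sh_only
    folds = rng.uniform(*config.fold_range, size=config.n_genes)
    folds *= np.where(rng.random(config.n_genes) < 0.5, 1.0, -1.0)

    mean_sh = base.copy()
    mean_yk = base.copy()
    mean_yk[is_de] = base[is_de] * 2.0 ** folds[is_de]
    mean_sh[is_pav & ~pav_side] = 0.0
    mean_yk[is_pav & pav_side] = 0.0

    r = 1.0 / config.dispersion

    def draw(means):
        out = np.zeros_like(means, dtype=np.int64)
        pos_mask = means > 0
        p = r / (r + means[pos_mask])
        out[pos_mask] = rng.negative_binomial(r, p)
        return out

    table = pd.DataFrame(
        {"gene_id": names, "count_SH": draw(mean_sh), "count_YK": draw(mean_yk)}
    )
    for i, name in enumerate(names):
        if is_pav[i]:
            truth.true_pav[name] = "sh_only" if pav_side[i] else "yk_only"
        else:
            truth.true_pav[name] = "both"
            if is_de[i]:
                truth.true_fold[name] = float(folds[i])
    return table, truth


def simulate_metabolome(config: SimConfig):
    """Long-format relative-concentration table for SH, YK, and F1.

    Experiment 1 measures the two parents with ``metab_n1`` replicates;
    experiment 2 measures parents and F1 with ``metab_n2`` replicates.
    Per metabolite the F1 mean is the mid-parent value (additive), one
    parent's value (dominant), or beyond the extreme parent by
    ``transgressive_margin`` (transgressive, direction per the mix).
    Replicates are lognormal with coefficient of variation ``cv_metab``;
    experiment 2 applies a per-metabolite lognormal environmental shift.
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_METAB, config.seed])
    n = config.n_metabolites
    names = [f"met{i:04d}" for i in range(1, n + 1)]
    compound = rng.choice(
        ["carbohydrate", "fatty_acid", "amino_acid", "other"],
        size=n,
        p=[0.20, 0.15, 0.05, 0.60],
    )
    mode = rng.choice(HETEROSIS_MODES, size=n, p=list(config.heterosis_mix))

    base = rng.lognormal(np.log(500.0), 1.0, size=n)
    ratio = rng.uniform(*config.parental_ratio_range, size=n)
    yk_high = rng.random(n) < 0.5
    mean_sh = np.where(yk_high, base, base * ratio)
    mean_yk = np.where(yk_high, base * ratio, base)

    mid = (mean_sh + mean_yk) / 2.0
    hi = np.maximum(mean_sh, mean_yk)
    lo = np.minimum(mean_sh, mean_yk)
    dom_parent = rng.random(n) < 0.5
    mean_f1 = np.where(
        mode == "additive",
        mid,
        np.where(
            mode == "dominant",
            np.where(dom_parent, mean_sh, mean_yk),
            np.where(
                mode == "transgressive_up",
                hi * (1.0 + config.transgressive_margin),
                lo * (1.0 - config.transgressive_margin),
            ),
        ),
    )

    absent = rng.random(n) < config.parent_absent_fraction
    absent_parent = np.where(rng.random(n) < 0.5, "SH", "YK")

    shift = rng.lognormal(0.0, config.exp_shift_sigma, size=n)
    sd_log = np.sqrt(np.log1p(config.cv_metab**2))

    truth = GroundTruth()
    rows = []
    for i, name in enumerate(names):
        means = {"SH": mean_sh[i], "YK": mean_yk[i], "F1": mean_f1[i]}
        if absent[i]:
            means[absent_parent[i]] = 0.0
            truth.metab_parent_absent[name] = str(absent_parent[i])
        truth.metab_class[name] = (
            str(mode[i]), float(means["SH"]), float(means["YK"]), float(means["F1"])
        )
        for experiment, genotypes, n_rep, mult in (
            (1, ("SH", "YK"), config.metab_n1, 1.0),
            (2, ("SH", "YK", "F1"), config.metab_n2, shift[i]),
        ):
            for genotype in genotypes:
                m = means[genotype] * mult
                if m > 0:
                    vals = m * np.exp(rng.normal(0.0, sd_log, n_rep) - sd_log**2 / 2.0)
                else:
                    vals = np.zeros(n_rep)
                for rep, v in enumerate(vals, start=1):
                    rows.append((name, compound[i], experiment, genotype, rep, float(v)))
    table = pd.DataFrame(
        rows, columns=["metabolite", "class", "experiment", "genotype", "replicate", "value"]
    )
    return table, truth


def simulate_qpcr(config: SimConfig):
    """Dilution-series and sample CT tables.

    The dilution series covers five fivefold steps per primer pair with
    ``qpcr_tech_reps`` technical replicates; CT = intercept +
    slope * log10(concentration) + Normal(0, qpcr_sd).  The sample table
    holds target and reference-gene CTs per accession; one target is
    absent in SH and carries a missing CT there (no-amplification
    sentinel, never CT=0).
    """
    config.validate()
    rng = np.random.default_rng([_STREAM_QPCR, config.seed])
    concentrations = 1.0 / 5.0 ** np.arange(5)
    primers = [f"target{i:02d}" for i in range(1, config.qpcr_n_targets + 1)] + ["reference"]

    dil_rows = []
    for primer in primers:
        for conc in concentrations:
            mu = config.qpcr_intercept + config.qpcr_slope * np.log10(conc)
            for rep in range(1, config.qpcr_tech_reps + 1):
                ct = mu + rng.normal(0.0, config.qpcr_sd)
                dil_rows.append((primer, conc, rep, float(ct)))
    dilutions = pd.DataFrame(dil_rows, columns=["primer", "concentration", "replicate", "ct"])

    efficiency = 10.0 ** (-1.0 / config.qpcr_slope) - 1.0
    sample_rows = []
    for i, primer in enumerate(primers[:-1]):
        # true YK/SH expression ratio; the last target is absent in SH
        log2_ratio = rng.normal(0.0, 3.0)
        absent_sh = i == config.qpcr_n_targets - 1
        for accession in ("SH", "YK"):
            for rep in range(1, config.qpcr_tech_reps + 1):
                ct_ref = 18.0 + rng.normal(0.0, config.qpcr_sd)
                if absent_sh and accession == "SH":
                    ct_t = np.nan
                else:
                    delta = -(log2_ratio if accession == "YK" else 0.0) * np.log(2.0) / np.log(
                        1.0 + efficiency
                    )
                    ct_t = ct_ref + 3.0 + delta + rng.normal(0.0, config.qpcr_sd)
                sample_rows.append((primer, accession, rep, ct_t, float(ct_ref)))
    samples = pd.DataFrame(
        sample_rows, columns=["gene", "accession", "replicate", "ct_target", "ct_reference"]
    )
    return dilutions, samples
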