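"""SNP calling between two inbred accessions from paired pileups.

Candidate substitution sites are emitted where the two accessions'
consensus bases differ at sufficient depth and mapping quality.  Each
candidate is then annotated by a cascade of removal filters — within-
accession heterozygosity, non-biallelism, low alternative-read support,
low alternative-allele fraction, reference discordance — followed by a
sliding-window cluster filter that removes variants packed more densely
than ``cluster_max_snps`` per ``cluster_window_bp`` (the signature of
reads misaligned around indel polymorphisms).  Filters annotate rather
than drop, so the PASS set is independent of evaluation order.

Site quality is a Phred-scaled score from a symmetric binomial error
model comparing the two-fixed-alleles hypothesis against a shared
single allele, capped at 999; calls at the cap form the high-quality
tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

QUALITY_CAP = 999.0
_QUALITY_ERROR_RATE = 1e-3

CASCADE_FILTERS = (
    "het_within_accession",
    "not_biallelic",
    "low_alt_reads",
    "low_alt_fraction",
    "ref_discordant",
)
CLUSTER_FILTER = "snp_cluster"


class PileupOrderError(ValueError):
    """Input sites are not sorted by (seq_id, pos)."""


class PileupFormatError(ValueError):
    """Malformed pileup record (e.g. non-ACGT reference base)."""


@dataclass(frozen=True)
class PileupSite:
    """Per-position base counts for both accessions (1-based coordinates)."""

    seq_id: str
    pos: int
    ref_base: str
    counts_a1: Mapping[str, int]
    counts_a2: Mapping[str, int]
    mapq: float = 60.0


@dataclass
class VariantCall:
    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth_a1: int
    depth_a2: int
    alt_fraction: float
    quality: float
    tier: str = "standard"                     # "standard" | "high_quality"
    filters: set[str] = field(default_factory=set)
    counts_a1: tuple[int, int, int, int] = (0, 0, 0, 0)
    counts_a2: tuple[int, int, int, int] = (0, 0, 0, 0)

    @property
    def passed(self) -> bool:
        return not self.filters


@dataclass(frozen=True)
class FilterConfig:
    min_mapq: float = 15.0
    min_depth: int = 3
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.10
    monomorphic_max_minor_fraction: float = 0.10
    # minor-allele evidence below this read count is treated as sequencing
    # noise, not heterozygosity (same support floor as min_alt_reads)
    het_min_minor_reads: int = 3
    cluster_max_snps: int = 4
    cluster_window_bp: int = 100
    require_ref_concordance: bool = True
    # "pooled": alt fraction over reads of both accessions combined;
    # "per_accession": over the alt-carrying accession only
    alt_fraction_mode: str = "pooled"

    def validate(self) -> None:
        if min(self.min_mapq, self.min_depth, self.min_alt_reads) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 <= self.min_alt_fraction <= 1:
            raise ValueError("min_alt_fraction must be in [0, 1]")
        if self.cluster_window_bp < 1:
            raise ValueError("cluster_window_bp must be >= 1")
        if self.alt_fraction_mode not in ("pooled", "per_accession"):
            raise ValueError("alt_fraction_mode must be 'pooled' or 'per_accession'")


@dataclass(frozen=True)
class ConcordanceReport:
    n_a: int
    n_b: int
    shared_positions: int
    allele_matches: int
    match_fraction: float
    unique_to_a: int
    unique_to_b: int


def _counts_array(counts: Mapping[str, int]) -> np.ndarray:
    arr = np.zeros(4, dtype=np.int64)
    for base, c in counts.items():
        if base not in _BASE_INDEX:
            raise PileupFormatError(f"non-ACGT base {base!r} in counts")
        if c < 0:
            raise PileupFormatError(f"negative count for base {base!r}")
        arr[_BASE_INDEX[base]] = c
    return arr


def _phred_quality(c1: np.ndarray, c2: np.ndarray, cons1: int, cons2: int) -> float:
    """Phred-scaled support for two fixed distinct alleles vs one shared allele."""
    e = _QUALITY_ERROR_RATE
    log_match, log_mis = np.log(1 - e), np.log(e / 3.0)

    def loglik(counts, allele):
        return counts[allele] * log_match + (counts.sum() - counts[allele]) * log_mis

    ll_diff = loglik(c1, cons1) + loglik(c2, cons2)
    ll_same = max(loglik(c1, a) + loglik(c2, a) for a in range(4))
    q = 10.0 / np.log(10.0) * (ll_diff - ll_same)
    return float(min(max(q, 0.0), QUALITY_CAP))


def _make_call(seq_id, pos, ref_code, c1, c2) -> VariantCall:
    cons1 = int(np.argmax(c1))
    cons2 = int(np.argmax(c2))
    alt = cons2 if cons2 != ref_code else cons1
    d1, d2 = int(c1.sum()), int(c2.sum())
    alt_reads = int(c1[alt] + c2[alt])
    q = _phred_quality(c1, c2, cons1, cons2)
    return VariantCall(
        seq_id=seq_id,
        pos=int(pos),
        ref_allele=BASES[ref_code],
        alt_allele=BASES[alt],
        depth_a1=d1,
        depth_a2=d2,
        alt_fraction=alt_reads / (d1 + d2) if d1 + d2 else 0.0,
        quality=q,
        tier="high_quality" if q >= QUALITY_CAP else "standard",
        counts_a1=tuple(int(x) for x in c1),
        counts_a2=tuple(int(x) for x in c2),
    )


def call_candidate_snps(
    sites: Sequence[PileupSite], config: FilterConfig | None = None
) -> list[VariantCall]:
    """Emit a candidate wherever the two accessions' consensus bases differ.

    Requires sites sorted by (seq_id, pos); both depths must reach
    ``min_depth`` and the site mapq must reach ``min_mapq``.  Consensus
    ties break to the alphabetically first base.
    """
    config = config or FilterConfig()
    config.validate()
    calls: list[VariantCall] = []
    prev: tuple[str, int] | None = None
    for site in sites:
        key = (site.seq_id, site.pos)
        if prev is not None and site.seq_id == prev[0] and site.pos <= prev[1]:
            raise PileupOrderError(
                f"sites not sorted at {site.seq_id}:{site.pos} (after {prev[0]}:{prev[1]})"
            )
        prev = key
        if site.ref_base not in _BASE_INDEX:
            raise PileupFormatError(
                f"non-ACGT reference base {site.ref_base!r} at {site.seq_id}:{site.pos}"
            )
        if site.pos < 1:
            raise PileupFormatError(f"non-positive position {site.pos} on {site.seq_id}")
        c1 = _counts_array(site.counts_a1)
        c2 = _counts_array(site.counts_a2)
        if c1.sum() < config.min_depth or c2.sum() < config.min_depth:
            continue
        if site.mapq < config.min_mapq:
            continue
        if int(np.argmax(c1)) == int(np.argmax(c2)):
            continue
        calls.append(_make_call(site.seq_id, site.pos, _BASE_INDEX[site.ref_base], c1, c2))
    return calls


def call_candidates_from_frames(
    pileup_a1: pd.DataFrame, pileup_a2: pd.DataFrame, config: FilterConfig | None = None
) -> list[VariantCall]:
    """Vectorized candidate detection on paired 9-column pileup frames."""
    config = config or FilterConfig()
    config.validate()
    if len(pileup_a1) != len(pileup_a2):
        raise PileupFormatError("pileup frames differ in length")
    if not (
        pileup_a1["seq_id"].to_numpy() == pileup_a2["seq_id"].to_numpy()
    ).all() or not (pileup_a1["pos"].to_numpy() == pileup_a2["pos"].to_numpy()).all():
        raise PileupFormatError("pileup frames are not position-aligned")

    base_cols = list(BASES)
    c1 = pileup_a1[base_cols].to_numpy(dtype=np.int64)
    c2 = pileup_a2[base_cols].to_numpy(dtype=np.int64)
    ref = pileup_a1["ref"].map(_BASE_INDEX)
    if ref.isna().any():
        bad = int(np.flatnonzero(ref.isna().to_numpy())[0])
        raise PileupFormatError(f"non-ACGT reference base in row {bad}")
    ref = ref.to_numpy(dtype=np.int64)
    mapq = np.minimum(
        pileup_a1["mapq"].to_numpy(dtype=float), pileup_a2["mapq"].to_numpy(dtype=float)
    )

    seq = pileup_a1["seq_id"].to_numpy()
    pos = pileup_a1["pos"].to_numpy(dtype=np.int64)
    order_ok = np.ones(len(pos), dtype=bool)
    same = seq[1:] == seq[:-1]
    order_ok[1:] = ~same | (pos[1:] > pos[:-1])
    if not order_ok.all():
        bad = int(np.flatnonzero(~order_ok)[0])
        raise PileupOrderError(f"sites not sorted at {seq[bad]}:{pos[bad]}")

    cons1 = c1.argmax(axis=1)
    cons2 = c2.argmax(axis=1)
    d1 = c1.sum(axis=1)
    d2 = c2.sum(axis=1)
    cand = (
        (cons1 != cons2)
        & (d1 >= config.min_depth)
        & (d2 >= config.min_depth)
        & (mapq >= config.min_mapq)
    )
    return [
        _make_call(seq[i], pos[i], ref[i], c1[i], c2[i]) for i in np.flatnonzero(cand)
    ]


def apply_cascade(
    candidates: Iterable[VariantCall], config: FilterConfig | None = None
) -> list[VariantCall]:
    """Annotate every candidate with the removal filters it fails.

    Annotation is total and per-site, so evaluation order cannot change
    the PASS set.  Biallelism is judged on the alleles in play at the
    site: reference, alternative, and each accession's consensus.
    """
    config = config or FilterConfig()
    config.validate()
    out = []
    for call in candidates:
        c1 = np.asarray(call.counts_a1, dtype=np.int64)
        c2 = np.asarray(call.counts_a2, dtype=np.int64)
        failed = set(call.filters) - set(CASCADE_FILTERS)

        for counts in (c1, c2):
            total = counts.sum()
            if total > 0:
                second = np.sort(counts)[-2]  # minor-allele read count
                if (
                    second / total > config.monomorphic_max_minor_fraction
                    and second >= config.het_min_minor_reads
                ):
                    failed.add("het_within_accession")

        cons1 = int(np.argmax(c1))
        cons2 = int(np.argmax(c2))
        alleles = {
            _BASE_INDEX[call.ref_allele], _BASE_INDEX[call.alt_allele], cons1, cons2
        }
        if len(alleles) > 2:
            failed.add("not_biallelic")

        alt = _BASE_INDEX[call.alt_allele]
        alt_reads = int(c1[alt] + c2[alt])
        if alt_reads < config.min_alt_reads:
            failed.add("low_alt_reads")
        if config.alt_fraction_mode == "pooled":
            denom = int(c1.sum() + c2.sum())
        else:
            denom = int(c2.sum() if c2[alt] >= c1[alt] else c1.sum())
            alt_reads = int(max(c1[alt], c2[alt]))
        if denom > 0 and alt_reads / denom < config.min_alt_fraction:
            failed.add("low_alt_fraction")

        if config.require_ref_concordance and BASES[cons1] != call.ref_allele:
            failed.add("ref_discordant")

        out.append(replace(call, filters=failed))
    return out


def cluster_filter(
    calls: Sequence[VariantCall], config: FilterConfig | None = None
) -> list[VariantCall]:
    """Flag PASS candidates falling in over-dense windows as snp_cluster.

    A call is flagged when any window of ``cluster_window_bp``
    consecutive bases contains strictly more than ``cluster_max_snps``
    PASS candidates.  Two-pointer sweep over candidate positions; every
    maximal window is anchored at some candidate, so this equals the
    exhaustive all-windows evaluation.
    """
    config = config or FilterConfig()
    config.validate()
    out = [replace(c, filters=set(c.filters) - {CLUSTER_FILTER}) for c in calls]
    by_seq: dict[str, list[int]] = {}
    for i, call in enumerate(out):
        if call.passed:
            by_seq.setdefault(call.seq_id, []).append(i)
    w, k = config.cluster_window_bp, config.cluster_max_snps
    for idxs in by_seq.values():
        pos = [out[i].pos for i in idxs]
        if pos != sorted(pos):
            raise PileupOrderError("calls not sorted by position within seq_id")
        flag = [False] * len(idxs)
        j = 0
        for i in range(len(idxs)):
            while pos[j] < pos[i] - w + 1:
                j += 1
            if i - j + 1 > k:
                for t in range(j, i + 1):
                    flag[t] = True
        for t, f in zip(idxs, flag):
            if f:
                out[t].filters.add(CLUSTER_FILTER)
    return out


def call_snps(
    pileup_a1: pd.DataFrame, pileup_a2: pd.DataFrame, config: FilterConfig | None = None
) -> list[VariantCall]:
    """Full pipeline: candidates -> removal cascade -> cluster filter."""
    config = config or FilterConfig()
    candidates = call_candidates_from_frames(pileup_a1, pileup_a2, config)
    return cluster_filter(apply_cascade(candidates, config), config)


# ---------------------------------------------------------------------------
# VCF output and concordance


_VCF_FILTER_DESCRIPTIONS = {
    "het_within_accession": "Minor-allele read fraction above the monomorphism "
    "threshold within at least one accession",
    "not_biallelic": "More than two alleles among reference, alternative, and "
    "the two accession consensus bases",
    "low_alt_reads": "Alternative allele supported by fewer reads than the minimum",
    "low_alt_fraction": "Alternative allele below the minimum fraction of aligned reads",
    "ref_discordant": "Accession-1 consensus differs from the reference base",
    CLUSTER_FILTER: "Variant inside an over-dense SNP window",
}


def write_vcf(
    calls: Sequence[VariantCall],
    path,
    contigs: Mapping[str, int] | None = None,
    source: str = "nightcontrast",
) -> None:
    """Write calls as VCF v4.2 (1-based positions, sorted).

    FILTER is PASS or the semicolon-joined failed-filter labels; INFO
    carries both depths, the alternative-allele fraction, the quality
    tier, and per-accession ACGT base counts so a round trip preserves
    every call field.
    """
    ordered = sorted(calls, key=lambda c: (c.seq_id, c.pos))
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
    ]
    for fid, desc in _VCF_FILTER_DESCRIPTIONS.items():
        lines.append(f'##FILTER=<ID={fid},Description="{desc}">')
    lines += [
        '##INFO=<ID=DP1,Number=1,Type=Integer,Description="Read depth, accession 1">',
        '##INFO=<ID=DP2,Number=1,Type=Integer,Description="Read depth, accession 2">',
        '##INFO=<ID=AF2,Number=1,Type=Float,Description="Alternative allele read fraction">',
        '##INFO=<ID=TIER,Number=1,Type=String,Description="Quality tier (standard or high_quality)">',
        '##INFO=<ID=BC1,Number=4,Type=Integer,Description="ACGT base counts, accession 1">',
        '##INFO=<ID=BC2,Number=4,Type=Integer,Description="ACGT base counts, accession 2">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in ordered:
        filt = "PASS" if c.passed else ";".join(sorted(c.filters))
        info = (
            f"DP1={c.depth_a1};DP2={c.depth_a2};AF2={c.alt_fraction:.6g};"
            f"TIER={c.tier};BC1={','.join(map(str, c.counts_a1))};"
            f"BC2={','.join(map(str, c.counts_a2))}"
        )
        lines.append(
            f"{c.seq_id}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t"
            f"{c.quality:.6g}\t{filt}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> list[VariantCall]:
    """Read calls back from a VCF written by :func:`write_vcf` (via pysam)."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = set(rec.filter.keys()) - {"PASS"}
            info = rec.info
            calls.append(
                VariantCall(
                    seq_id=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    depth_a1=int(info["DP1"]),
                    depth_a2=int(info["DP2"]),
                    alt_fraction=float(info["AF2"]),
                    quality=float(rec.qual),
                    tier=str(info["TIER"]),
                    filters=filters,
                    counts_a1=tuple(int(x) for x in info["BC1"]),
                    counts_a2=tuple(int(x) for x in info["BC2"]),
                )
            )
    return calls


def concordance(
    calls_a: Sequence[VariantCall], calls_b: Sequence[VariantCall]
) -> ConcordanceReport:
    """Positional and allele-level agreement between two call sets."""
    a = {(c.seq_id, c.pos): (c.ref_allele, c.alt_allele) for c in calls_a}
    b = {(c.seq_id, c.pos): (c.ref_allele, c.alt_allele) for c in calls_b}
    shared = set(a) & set(b)
    matches = sum(1 for k in shared if a[k] == b[k])
    return ConcordanceReport(
        n_a=len(a),
        n_b=len(b),
        shared_positions=len(shared),
        allele_matches=matches,
        match_fraction=matches / len(shared) if shared else float("nan"),
        unique_to_a=len(set(a) - set(b)),
        unique_to_b=len(set(b) - set(a)),
    )


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [c.seq_id for c in calls],
            "pos": [c.pos for c in calls],
            "ref": [c.ref_allele for c in calls],
            "alt": [c.alt_allele for c in calls],
            "depth_a1": [c.depth_a1 for c in calls],
            "depth_a2": [c.depth_a2 for c in calls],
            "alt_fraction": [c.alt_fraction for c in calls],
            "quality": [c.quality for c in calls],
            "tier": [c.tier for c in calls],
            "filters": [";".join(sorted(c.filters)) or "PASS" for c in calls],
        }
    )
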