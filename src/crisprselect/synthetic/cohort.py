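"""Synthetic tumor cohorts with planted statistical structure.

Generates the three linked tables the cohort arm consumes — somatic
mutations, allele-specific copy-number segments, and clinical data —
with known ground truth: heterogeneous per-gene/per-sample alteration
probabilities, planted mutually exclusive or cooccurring gene pairs,
platform-specific mutation-burden scales, a locus-restricted
trinucleotide mutation spectrum drawn from a supplied signature matrix,
and exponential survival with group-specific hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..sbs import CHANNELS96, COMPLEMENT as _COMPLEMENT, SUB_TYPES, sbs96_channels

#: default per-gene marginal alteration rates, loosely shaped like a
#: muscle-invasive bladder cancer panel (TP53 ~50%, ERCC2 ~10%, ...)
DEFAULT_GENE_RATES: dict[str, float] = {
    "TP53": 0.50,
    "KMT2D": 0.28,
    "KDM6A": 0.26,
    "ARID1A": 0.25,
    "PIK3CA": 0.22,
    "RB1": 0.20,
    "FGFR3": 0.14,
    "STAG2": 0.14,
    "ERCC2": 0.10,
    "ERBB2": 0.12,
    "ELF3": 0.12,
    "HRAS": 0.06,
    "SF3B1": 0.06,
}

#: protein lengths (residues) used for placing protein positions
GENE_LENGTHS: dict[str, int] = {
    "TP53": 393, "KMT2D": 5537, "KDM6A": 1401, "ARID1A": 2285,
    "PIK3CA": 1068, "RB1": 928, "FGFR3": 806, "STAG2": 1231,
    "ERCC2": 760, "ERBB2": 1255, "ELF3": 371, "HRAS": 189, "SF3B1": 1304,
}

from ..cohort import DEFAULT_HELICASE_INTERVALS_CONFIG as DEFAULT_HELICASE_INTERVALS

DEFAULT_LOCUS = ("chr19", 45_349_837, 45_370_000)  # ERCC2-sized window

PASSING_CLASSES = ("missense", "stopgain", "frameshift", "nonstop", "splice")


def make_synthetic_signatures(
    names: Sequence[str] = ("SIG-A", "SIG-B", "SIG-C", "SIG-D"),
    seed: int = 96,
    concentration: float = 0.15,
) -> pd.DataFrame:
    """Synthetic 96-channel signature matrix (columns sum to 1).

    Sparse Dirichlet profiles standing in for published COSMIC
    signatures, which are not redistributed here; suitable for testing
    spectrum construction and NNLS refitting.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for name in names:
        profile = rng.dirichlet(np.full(96, concentration))
        cols[name] = profile / profile.sum()
    return pd.DataFrame(cols, index=CHANNELS96)


@dataclass
class CohortBundle:
    """Mutation, copy-number and clinical tables plus the locus reference."""

    mutations: pd.DataFrame
    segments: pd.DataFrame
    clinical: pd.DataFrame
    locus: tuple[str, int, int] = DEFAULT_LOCUS
    locus_reference: str = ""

    def validate(self) -> None:
        samples = set(self.clinical["sample"])
        assert set(self.mutations["sample"]) <= samples
        assert set(self.segments["sample"]) <= samples
        assert (self.segments["minor_cn"] <= self.segments["major_cn"]).all()

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("mutations", self.mutations),
            ("segments", self.segments),
            ("clinical", self.clinical),
        ):
            paths[name] = out_dir / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False)
        chrom, start, _ = self.locus
        fasta = out_dir / "locus.fa"
        with open(fasta, "w") as fh:
            fh.write(f">{chrom}:{start}\n")
            for i in range(0, len(self.locus_reference), 80):
                fh.write(self.locus_reference[i : i + 80] + "\n")
        paths["locus_reference"] = fasta
        return paths

    @classmethod
    def read(cls, out_dir: str | Path) -> "CohortBundle":
        out_dir = Path(out_dir)
        mutations = pd.read_csv(out_dir / "mutations.tsv", sep="\t")
        segments = pd.read_csv(out_dir / "segments.tsv", sep="\t")
        clinical = pd.read_csv(out_dir / "clinical.tsv", sep="\t")
        for df in (mutations, clinical):
            if "panel_version" in df.columns:
                df["panel_version"] = (
                    df["panel_version"].fillna("").astype(str)
                    .str.replace(r"\.0$", "", regex=True)
                )
        lines = (out_dir / "locus.fa").read_text().splitlines()
        chrom, start = lines[0][1:].split(":")
        seq = "".join(lines[1:])
        return cls(
            mutations, segments, clinical,
            locus=(chrom, int(start), int(start) + len(seq) - 1),
            locus_reference=seq,
        )


@dataclass
class CohortTruth:
    alteration: pd.DataFrame  # genes x samples, 0/1, before class filtering
    p_ij: pd.DataFrame
    planted_pairs: tuple
    loh_samples: tuple[str, ...]
    hazards: dict[str, float]
    exposures: dict[str, float]
    channel_counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None


def _pyrimidine_context(seq: str, i: int) -> tuple[str, str] | None:
    """(central pyrimidine, 5'-3' context) at position i, strand-collapsed."""
    if i < 1 or i >= len(seq) - 1:
        return None
    tri = seq[i - 1 : i + 2]
    if any(b not in "ACGT" for b in tri):
        return None
    if tri[1] in "CT":
        return tri[1], tri
    rc = tri.translate(_COMPLEMENT)[::-1]
    return rc[1], rc


def _channel_position_index(seq: str) -> dict[str, list[int]]:
    """Map pyrimidine trinucleotide context -> 0-based positions in seq."""
    index: dict[str, list[int]] = {}
    for i in range(1, len(seq) - 1):
        ctx = _pyrimidine_context(seq, i)
        if ctx is None:
            continue
        index.setdefault(ctx[1], []).append(i)
    return index


def simulate_cohort(
    n_samples: int = 400,
    gene_rates: Mapping[str, float] | None = None,
    sample_rate_dispersion: float = 0.5,
    planted_pairs: Sequence[tuple[str, str, str, float]] = (),
    platforms: Sequence[tuple[str, str | None, float]] = (
        ("WES", None, 0.5),
        ("MSK", "410", 0.3),
        ("Caris", None, 0.2),
    ),
    survival: Mapping[str, float] | None = None,
    censoring_rate: float = 0.01,
    response_rates: Mapping[str, float] | None = None,
    signature_matrix: pd.DataFrame | None = None,
    signature_mixture: Mapping[str, float] | None = None,
    locus: tuple[str, int, int] = DEFAULT_LOCUS,
    locus_gene: str = "ERCC2",
    helicase_intervals: Sequence[tuple[int, int]] = DEFAULT_HELICASE_INTERVALS,
    helicase_fraction: float = 0.87,
    missense_fraction: float = 0.93,
    loh_fraction: float = 0.06,
    mean_tmb: float = 5.0,
    tmb_log_sd: float = 0.4,
    platform_tmb_bias: Mapping[str, float] | None = None,
    benign_extra_rate: float = 0.1,
    tables: bool = True,
    seed: int = 0,
) -> tuple[CohortBundle, CohortTruth]:
    """Simulate a cohort with planted structure; see module docstring.

    ``platforms`` is (platform, panel_version, fraction-of-samples);
    ``survival`` maps locus-gene status (``MUT``/``WT``) to exponential
    hazards per month; ``planted_pairs`` entries are
    (geneA, geneB, 'exclusive'|'cooccurring', strength in [0,1]).
    With ``tables=False`` only the alteration matrix and its truth are
    generated (for large calibration studies); the bundle tables are
    empty.
    """
    rng = np.random.default_rng(seed)
    gene_rates = dict(DEFAULT_GENE_RATES if gene_rates is None else gene_rates)
    survival = dict({"MUT": 0.035, "WT": 0.06} if survival is None else survival)
    response_rates = dict(
        {"MUT": 0.70, "WT": 0.35} if response_rates is None else response_rates
    )
    platform_tmb_bias = dict(
        {"WES": 1.0, "MSK": 1.4, "Caris": 1.6, "Oncopanel": 1.4}
        if platform_tmb_bias is None
        else platform_tmb_bias
    )
    if not all(0 <= r <= 1 for r in gene_rates.values()):
        raise ValueError("gene rates must lie in [0,1]")
    if any(h <= 0 for h in survival.values()):
        raise ValueError("hazards must be positive")
    for a, b, direction, strength in planted_pairs:
        for g in (a, b):
            if g not in gene_rates:
                raise ValueError(f"unknown gene in planted pair: {g}")
        if direction not in ("exclusive", "cooccurring"):
            raise ValueError(f"unknown direction {direction!r}")

    genes = list(gene_rates)
    samples = [f"S{i:05d}" for i in range(n_samples)]

    # heterogeneous per-sample alteration propensity (logit offsets)
    offsets = (
        rng.normal(0.0, sample_rate_dispersion, size=n_samples)
        if sample_rate_dispersion > 0
        else np.zeros(n_samples)
    )
    logit = lambda p: np.log(p / (1 - p))
    p_ij = 1.0 / (
        1.0 + np.exp(-(logit(np.array([gene_rates[g] for g in genes]))[:, None] + offsets[None, :]))
    )
    A = (rng.random(p_ij.shape) < p_ij).astype(np.int8)
    gene_idx = {g: i for i, g in enumerate(genes)}

    for a, b, direction, strength in planted_pairs:
        ia, ib = gene_idx[a], gene_idx[b]
        if direction == "exclusive":
            both = np.flatnonzero((A[ia] == 1) & (A[ib] == 1))
            resolve = both[rng.random(both.size) < strength]
            drop_a = rng.random(resolve.size) < 0.5
            A[ia, resolve[drop_a]] = 0
            A[ib, resolve[~drop_a]] = 0
        else:
            only = np.flatnonzero(A[ia] != A[ib])
            copy = only[rng.random(only.size) < strength]
            A[ia, copy] = 1
            A[ib, copy] = 1

    if not tables:
        empty = pd.DataFrame()
        bundle = CohortBundle(
            mutations=empty, segments=empty, clinical=empty,
            locus=locus, locus_reference="",
        )
        truth = CohortTruth(
            alteration=pd.DataFrame(A, index=genes, columns=samples),
            p_ij=pd.DataFrame(p_ij, index=genes, columns=samples),
            planted_pairs=tuple(planted_pairs),
            loh_samples=(), hazards=survival, exposures={}, seed=seed,
        )
        return bundle, truth

    if locus_gene not in gene_rates:
        raise ValueError(f"locus gene {locus_gene!r} not among simulated genes")

    # --- locus reference and spectrum machinery ---------------------------
    chrom, locus_start, locus_end = locus
    locus_len = locus_end - locus_start + 1
    locus_seq = "".join(rng.choice(list("ACGT"), size=locus_len))
    ctx_index = _channel_position_index(locus_seq)

    if signature_matrix is None:
        signature_matrix = make_synthetic_signatures()
    if signature_mixture is None:
        cols = list(signature_matrix.columns)
        signature_mixture = {cols[0]: 0.6, cols[1]: 0.4}
    mix = np.zeros(96)
    for name, w in signature_mixture.items():
        mix += w * signature_matrix[name].to_numpy()
    mix = mix / mix.sum()

    def sample_locus_snv() -> tuple[int, str, str, str]:
        """(1-based genomic pos, ref, alt, channel) from the mixture."""
        while True:
            ch = CHANNELS96[rng.choice(96, p=mix)]
            ctx = ch[0] + ch[2] + ch[6]  # e.g. A[C>A]A -> ACA
            # ctx_index is keyed by the pyrimidine-strand context, so it
            # already covers both genome strands
            cands = ctx_index.get(ctx, [])
            if not cands:
                continue
            i = cands[int(rng.integers(len(cands)))]
            ref_genome = locus_seq[i]
            alt_pyr = ch[4]  # A[C>A]A -> alt on pyrimidine strand
            if ref_genome in "CT":
                alt_genome = alt_pyr
            else:
                alt_genome = alt_pyr.translate(_COMPLEMENT)
            return locus_start + i, ref_genome, alt_genome, ch

    # --- mutation rows ----------------------------------------------------
    mut_rows: list[dict] = []
    channel_counts: dict[str, int] = {}
    hd_len = sum(e - s + 1 for s, e in helicase_intervals)
    gene_len = GENE_LENGTHS.get(locus_gene, 760)

    def protein_pos_for_locus() -> int:
        if rng.random() < helicase_fraction:
            s, e = helicase_intervals[int(rng.integers(len(helicase_intervals)))]
            return int(rng.integers(s, e + 1))
        # outside all intervals
        while True:
            p = int(rng.integers(1, gene_len + 1))
            if not any(s <= p <= e for s, e in helicase_intervals):
                return p

    platform_names, platform_versions, platform_fracs = zip(*platforms)
    platform_assign = rng.choice(
        len(platforms), size=n_samples, p=np.array(platform_fracs) / sum(platform_fracs)
    )

    for j, sample in enumerate(samples):
        plat = platform_names[platform_assign[j]]
        version = platform_versions[platform_assign[j]]
        for g in genes:
            if not A[gene_idx[g], j]:
                # occasionally a benign variant the class filter must drop
                if rng.random() < benign_extra_rate * gene_rates[g]:
                    mut_rows.append(
                        dict(
                            sample=sample, gene=g, chrom="chr1",
                            pos=int(rng.integers(1_000_000, 2_000_000)),
                            ref="C", alt="T", variant_class="synonymous",
                            protein_pos=int(rng.integers(1, GENE_LENGTHS.get(g, 500))),
                            pathogenicity_label="benign", platform=plat,
                            panel_version=version if version else "",
                        )
                    )
                continue
            if g == locus_gene:
                pos, ref, alt, ch = sample_locus_snv()
                channel_counts[ch] = channel_counts.get(ch, 0) + 1
                u = rng.random()
                if u < missense_fraction:
                    vclass = "missense"
                else:
                    vclass = ("stopgain", "frameshift", "nonstop")[int(rng.integers(3))]
                row = dict(
                    sample=sample, gene=g, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    variant_class=vclass, protein_pos=protein_pos_for_locus(),
                    pathogenicity_label="likely_pathogenic", platform=plat,
                    panel_version=version if version else "",
                )
            else:
                vclass = PASSING_CLASSES[
                    int(rng.choice(len(PASSING_CLASSES), p=[0.8, 0.08, 0.08, 0.01, 0.03]))
                ]
                label = "pathogenic" if rng.random() < 0.6 else "likely_pathogenic"
                row = dict(
                    sample=sample, gene=g, chrom="chr1",
                    pos=int(rng.integers(1_000_000, 2_000_000)),
                    ref="C", alt="T", variant_class=vclass,
                    protein_pos=int(rng.integers(1, GENE_LENGTHS.get(g, 500) + 1)),
                    pathogenicity_label=label, platform=plat,
                    panel_version=version if version else "",
                )
            mut_rows.append(row)

    mutations = pd.DataFrame(mut_rows)

    # --- copy-number segments --------------------------------------------
    locus_mut_samples = [samples[j] for j in np.flatnonzero(A[gene_idx[locus_gene]])]
    n_loh = int(round(loh_fraction * len(locus_mut_samples)))
    loh_samples = tuple(
        sorted(
            np.array(locus_mut_samples)[
                rng.choice(len(locus_mut_samples), size=n_loh, replace=False)
            ]
        )
        if locus_mut_samples
        else ()
    )
    seg_rows = []
    for sample in samples:
        minor = 0 if sample in loh_samples else 1
        seg_rows.append(
            dict(
                sample=sample, chrom=chrom,
                start=locus_start - 50_000, end=locus_end + 50_000,
                major_cn=int(rng.integers(1, 4)) if minor == 0 else int(rng.integers(1, 3)),
                minor_cn=minor,
            )
        )
    segments = pd.DataFrame(seg_rows)
    segments["major_cn"] = segments[["major_cn", "minor_cn"]].max(axis=1)

    # --- clinical table ---------------------------------------------------
    mb_by_platform = {"WES": 38.0, "MSK": 1.016478, "Caris": 1.4, "Oncopanel": 0.826167}
    clin_rows = []
    for j, sample in enumerate(samples):
        plat = platform_names[platform_assign[j]]
        version = platform_versions[platform_assign[j]]
        status = "MUT" if A[gene_idx[locus_gene], j] else "WT"
        hazard = survival.get(status, survival["WT"])
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / censoring_rate) if censoring_rate > 0 else np.inf
        lam = np.exp(rng.normal(np.log(mean_tmb), tmb_log_sd))
        bias = platform_tmb_bias.get(plat, 1.0)
        mb = mb_by_platform.get(plat, 1.0)
        clin_rows.append(
            dict(
                sample=sample, cohort="synthetic", platform=plat,
                panel_version=version if version else "",
                time=round(min(t_event, t_cens), 3),
                event=int(t_event <= t_cens),
                response=(
                    "responder"
                    if rng.random() < response_rates.get(status, 0.5)
                    else "nonresponder"
                ),
                treatment="platinum",
                nonsyn_count=int(rng.poisson(lam * bias * mb)),
            )
        )
    clinical = pd.DataFrame(clin_rows)

    bundle = CohortBundle(
        mutations=mutations,
        segments=segments,
        clinical=clinical,
        locus=locus,
        locus_reference=locus_seq,
    )
    bundle.validate()
    truth = CohortTruth(
        alteration=pd.DataFrame(A, index=genes, columns=samples),
        p_ij=pd.DataFrame(p_ij, index=genes, columns=samples),
        planted_pairs=tuple(planted_pairs),
        loh_samples=loh_samples,
        hazards=survival,
        exposures=dict(signature_mixture),
        channel_counts=channel_counts,
        seed=seed,
    )
    return bundle, truth
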