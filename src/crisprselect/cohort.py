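"""Cohort-level genomic classifications and summaries.

Implements the tumor-side analyses around ERCC2 in bladder cancer:
helicase-domain mutation status, TP53 pathogenic status, loss of
heterozygosity from allele-specific copy-number segments, tumor
mutation burden with cross-platform harmonization, domain-enrichment
testing, and region-restricted 96-channel mutational-spectrum
construction with nonnegative least-squares signature refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .sbs import CHANNELS96, COMPLEMENT as _COMPLEMENT
from .stats import TestResult, chi_square_gof

logger = logging.getLogger(__name__)

MUT = "MUT"
WT = "WT"
LOH = "LOH"
NO_LOH = "no_LOH"
NA = "NA"

TRUNCATING_CLASSES = frozenset({"stopgain", "frameshift", "nonstop"})
QUALIFYING_CLASSES = frozenset({"missense"}) | TRUNCATING_CLASSES
PATHOGENIC_LABELS = frozenset({"pathogenic", "likely_pathogenic"})

#: helicase-domain residue intervals used when no configuration is given
#: (1-based inclusive; the two conserved ATPase/helicase lobes)
DEFAULT_HELICASE_INTERVALS_CONFIG: tuple[tuple[int, int], ...] = ((6, 260), (440, 730))

#: megabases of genome covered per sequencing platform / panel version
PLATFORM_MB: dict[tuple[str, str], float] = {
    ("WES", ""): 38.0,
    ("Oncopanel", "v1"): 0.753334,
    ("Oncopanel", "v2"): 0.826167,
    ("Oncopanel", "v3"): 1.315078,
    ("MSK", "341"): 0.896665,
    ("MSK", "410"): 1.016478,
    ("MSK", "468"): 1.139322,
    ("MSK", "505"): 1.25964,
    ("Caris", ""): 1.4,
}


# -- mutation status -------------------------------------------------------


def classify_ercc2_status(
    mutations: pd.DataFrame,
    helicase_intervals: Sequence[tuple[int, int]],
) -> str:
    """ERCC2 status of one sample's mutation rows.

    ``MUT`` iff at least one missense or truncating (stopgain,
    frameshift, nonstop) variant falls at a protein position inside a
    helicase-domain interval (1-based inclusive); variants outside the
    intervals, or of other classes, leave the sample ``WT``.
    """
    for s, e in helicase_intervals:
        if s > e:
            raise ValueError(f"malformed interval ({s},{e})")
    for _, row in mutations.iterrows():
        if row.get("gene", "ERCC2") != "ERCC2":
            continue
        if row["variant_class"] not in QUALIFYING_CLASSES:
            continue
        pos = row.get("protein_pos")
        if pos is None or (isinstance(pos, float) and np.isnan(pos)):
            warnings.warn(
                f"ERCC2 {row['variant_class']} variant without protein position "
                f"in sample {row.get('sample', '?')}; skipped",
                stacklevel=2,
            )
            continue
        if any(s <= pos <= e for s, e in helicase_intervals):
            return MUT
    return WT


def classify_tp53_status(
    mutations: pd.DataFrame, deep_deletion: bool = False
) -> str:
    """TP53 status: ``MUT`` iff a pathogenic/likely-pathogenic variant or a
    deep deletion is present; variants of uncertain significance stay WT."""
    if deep_deletion:
        return MUT
    for _, row in mutations.iterrows():
        if row.get("gene", "TP53") != "TP53":
            continue
        if str(row.get("pathogenicity_label", "")).lower() in PATHOGENIC_LABELS:
            return MUT
    return WT


def call_loh(
    gene_interval: tuple[str, int, int], segments: pd.DataFrame
) -> str:
    """LOH call for one sample at a gene locus.

    ``LOH`` iff any overlapping allele-specific copy-number segment has
    minor copy number 0; ``no_LOH`` if overlapping segments all retain
    the minor allele; ``NA`` if no segment overlaps the locus.
    Intervals are 1-based inclusive.
    """
    chrom, start, end = gene_interval
    if (segments["start"] > segments["end"]).any():
        bad = segments[segments["start"] > segments["end"]].iloc[0]
        raise ValueError(f"malformed segment: start {bad['start']} > end {bad['end']}")
    overlap = segments[
        (segments["chrom"] == chrom)
        & (segments["start"] <= end)
        & (segments["end"] >= start)
    ]
    if overlap.empty:
        return NA
    return LOH if (overlap["minor_cn"] == 0).any() else NO_LOH


# -- tumor mutation burden -------------------------------------------------


@dataclass
class TmbRecord:
    sample: str
    nonsyn_count: int
    covered_mb: float
    tmb: float
    platform: str
    panel_version: str = ""
    z: float | None = None


def compute_tmb(
    count: int, platform: str, panel_version: str = "", sample: str = ""
) -> TmbRecord:
    """Nonsynonymous mutations per megabase of covered genome."""
    key = (platform, str(panel_version))
    if key not in PLATFORM_MB:
        raise KeyError(
            f"unknown platform {platform!r} (version {panel_version!r}); "
            f"registered: {sorted(PLATFORM_MB)}"
        )
    if count < 0:
        raise ValueError("mutation count must be nonnegative")
    mb = PLATFORM_MB[key]
    return TmbRecord(
        sample=sample,
        nonsyn_count=int(count),
        covered_mb=mb,
        tmb=count / mb,
        platform=platform,
        panel_version=str(panel_version),
    )


def harmonize_tmb(records: Sequence[TmbRecord]) -> list[TmbRecord]:
    """Standardize TMB across platforms via within-stratum z-scores.

    Within each (platform, panel version) stratum, z is the sample
    standardization of log10(tmb + 1); the log transform tempers the
    right skew of mutation burden. Strata of size 1 or with zero spread
    get z = NaN with a warning.
    """
    by_stratum: dict[tuple[str, str], list[TmbRecord]] = {}
    for rec in records:
        by_stratum.setdefault((rec.platform, rec.panel_version), []).append(rec)
    out: list[TmbRecord] = []
    for stratum, recs in by_stratum.items():
        logs = np.log10(np.array([r.tmb for r in recs]) + 1.0)
        if len(recs) < 2 or logs.std(ddof=1) == 0:
            warnings.warn(
                f"stratum {stratum} has n={len(recs)} or zero spread; z undefined",
                stacklevel=2,
            )
            z = np.full(len(recs), np.nan)
        else:
            z = (logs - logs.mean()) / logs.std(ddof=1)
        for rec, zi in zip(recs, z):
            out.append(
                TmbRecord(
                    sample=rec.sample,
                    nonsyn_count=rec.nonsyn_count,
                    covered_mb=rec.covered_mb,
                    tmb=rec.tmb,
                    platform=rec.platform,
                    panel_version=rec.panel_version,
                    z=float(zi) if np.isfinite(zi) else None,
                )
            )
    return out


# -- mutational spectrum ---------------------------------------------------


def build_spectrum96(
    mutations: pd.DataFrame,
    reference: str,
    ref_start: int,
    chrom: str | None = None,
) -> pd.Series:
    """96-channel SBS spectrum of mutations inside a reference window.

    ``reference`` covers genomic positions starting at 1-based
    ``ref_start``. Only single-base substitutions count; purine-reference
    sites are collapsed onto the pyrimidine strand by reverse
    complement. Indels/MNVs are excluded (logged), and variants whose
    stated ref allele disagrees with the reference are skipped with a
    warning.
    """
    spectrum = pd.Series(0, index=CHANNELS96, dtype=int)
    n_non_snv = 0
    for _, row in mutations.iterrows():
        ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            n_non_snv += 1
            continue
        if chrom is not None and row.get("chrom") != chrom:
            continue
        i = int(row["pos"]) - ref_start  # 0-based index into reference
        if not 1 <= i <= len(reference) - 2:
            continue
        if reference[i] != ref:
            warnings.warn(
                f"ref allele mismatch at {row.get('chrom','?')}:{row['pos']} "
                f"({ref} vs reference {reference[i]}); variant skipped",
                stacklevel=2,
            )
            continue
        tri = reference[i - 1 : i + 2]
        if ref in "CT":
            channel = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
        else:
            rc_tri = tri.translate(_COMPLEMENT)[::-1]
            rc_alt = alt.translate(_COMPLEMENT)
            channel = f"{rc_tri[0]}[{rc_tri[1]}>{rc_alt}]{rc_tri[2]}"
        spectrum[channel] += 1
    if n_non_snv:
        logger.info("excluded %d non-SNV variants from spectrum", n_non_snv)
    return spectrum


@dataclass
class ExposureVector:
    exposures: pd.Series  # nonnegative weight per signature
    residual_norm: float

    def cosine_similarity(self, other: Mapping[str, float]) -> float:
        a = self.exposures.to_numpy(dtype=float)
        b = np.array([other.get(k, 0.0) for k in self.exposures.index])
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return float("nan")
        return float(a @ b / (na * nb))


def fit_signatures_nnls(
    spectrum: pd.Series | Sequence[float], signatures: pd.DataFrame
) -> ExposureVector:
    """Refit known signatures to a spectrum by nonnegative least squares.

    Minimizes ||C - S e||_2 subject to e >= 0 (Lawson-Hanson active
    set). Signature columns must be nonnegative and sum to 1.
    """
    S = signatures.to_numpy(dtype=float)
    if S.shape[1] == 0:
        raise ValueError("signature matrix has no columns")
    if np.any(S < 0):
        raise ValueError("signature entries must be nonnegative")
    if not np.allclose(S.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    c = np.asarray(
        spectrum.to_numpy() if isinstance(spectrum, pd.Series) else spectrum, dtype=float
    )
    if c.shape[0] != S.shape[0]:
        raise ValueError("spectrum length must match signature rows")
    if np.all(c == 0):
        return ExposureVector(
            exposures=pd.Series(0.0, index=signatures.columns), residual_norm=0.0
        )
    e, rnorm = nnls(S, c)
    return ExposureVector(
        exposures=pd.Series(e, index=signatures.columns), residual_norm=float(rnorm)
    )


# -- domain enrichment -----------------------------------------------------


def domain_enrichment_test(
    n_in_domain: int, n_total: int, domain_length_fraction: float
) -> TestResult:
    """Chi-square test of variant enrichment in a protein domain.

    Compares observed [in-domain, outside] counts with the proportions
    expected if variants fell uniformly along the protein.
    """
    if not 0 < domain_length_fraction < 1:
        raise ValueError("domain length fraction must lie in (0,1)")
    if n_in_domain > n_total:
        raise ValueError("in-domain count exceeds total")
    return chi_square_gof(
        [n_in_domain, n_total - n_in_domain],
        [domain_length_fraction, 1 - domain_length_fraction],
    )


# -- convenience over full cohort tables -----------------------------------


def cohort_status_table(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    helicase_intervals: Sequence[tuple[int, int]],
    segments: pd.DataFrame | None = None,
    locus: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Per-sample ERCC2/TP53 status (and LOH where segments are given)."""
    rows = []
    mut_by_sample = dict(tuple(mutations.groupby("sample"))) if len(mutations) else {}
    seg_by_sample = (
        dict(tuple(segments.groupby("sample"))) if segments is not None else {}
    )
    empty = mutations.iloc[0:0]
    for sample in clinical["sample"]:
        muts = mut_by_sample.get(sample, empty)
        row = {
            "sample": sample,
            "ercc2_status": classify_ercc2_status(
                muts[muts["gene"] == "ERCC2"] if len(muts) else muts, helicase_intervals
            ),
            "tp53_status": classify_tp53_status(
                muts[muts["gene"] == "TP53"] if len(muts) else muts
            ),
        }
        if segments is not None and locus is not None:
            segs = seg_by_sample.get(sample)
            row["ercc2_loh"] = call_loh(locus, segs) if segs is not None else NA
        rows.append(row)
    return pd.DataFrame(rows)
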