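"""Amplicon coordinate model for CRISPR knock-in experiments.

An :class:`AmpliconDesign` describes the sequenced amplicon around a Cas9
cut site: the reference sequence, its exon/intron structure, and the two
knock-in templates — the mutation of interest (Mut) and a synonymous
internal control (WT*) — each given as a set of single-base substitutions.
All downstream read classification and simulation shares this coordinate
frame.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

VALID_BASES = frozenset("ACGT")

EXON = "exon"
INTRON = "intron"

EXONIC = "exonic"
INTRONIC = "intronic"
SPLICE_SITE = "splice_site"

#: substitutions must sit within homology-arm reach of the cut site
HOMOLOGY_ARM_REACH = 60

#: width of the canonical splice donor/acceptor dinucleotide
SPLICE_SITE_WIDTH = 2


class DesignError(ValueError):
    """Base class for amplicon design validation failures."""


class RegionTilingError(DesignError):
    """Regions do not tile the reference without gaps or overlaps."""


class SubstitutionRefMismatch(DesignError):
    """A substitution's ref base disagrees with the reference sequence."""


class CutSiteOutOfRange(DesignError):
    """The cut site does not lie within the reference."""


Substitution = tuple[int, str, str]  # (position, ref_base, alt_base)


@dataclass(frozen=True)
class Region:
    start: int
    end: int
    kind: str  # exon | intron

    def __post_init__(self) -> None:
        if self.kind not in (EXON, INTRON):
            raise DesignError(f"unknown region kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise DesignError(f"bad region interval [{self.start},{self.end})")


@dataclass(frozen=True)
class AmpliconDesign:
    """Reference amplicon plus edit templates.

    Parameters
    ----------
    reference : uppercase DNA string.
    regions : ordered (start, end, kind) tuples tiling the reference.
    coding_frame_offset : frame (0-2) of the first exonic base.
    cut_site : 0-based position *between* bases; Cas9 cuts after base
        ``cut_site - 1``.
    mut_substitutions, wtstar_substitutions : the Mut and WT* template
        substitution sets as (position, ref, alt) triples.
    splice_sites : derived donor/acceptor dinucleotide intervals; filled
        in by :func:`validate_design`.
    """

    name: str
    reference: str
    regions: tuple[Region, ...]
    cut_site: int
    mut_substitutions: frozenset[Substitution]
    wtstar_substitutions: frozenset[Substitution]
    coding_frame_offset: int = 0
    splice_sites: tuple[tuple[int, int], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.reference)

    # -- template helpers -------------------------------------------------
    def apply_substitutions(self, subs: Iterable[Substitution]) -> str:
        seq = list(self.reference)
        for pos, _ref, alt in subs:
            seq[pos] = alt
        return "".join(seq)

    @property
    def mut_sequence(self) -> str:
        """Reference with the Mut template knocked in."""
        return self.apply_substitutions(self.mut_substitutions)

    @property
    def wtstar_sequence(self) -> str:
        """Reference with the WT* template knocked in."""
        return self.apply_substitutions(self.wtstar_substitutions)

    def region_at(self, pos: int) -> Region:
        for region in self.regions:
            if region.start <= pos < region.end:
                return region
        raise IndexError(f"position {pos} outside amplicon [0,{len(self)})")


def _as_regions(regions: Sequence) -> tuple[Region, ...]:
    out = []
    for r in regions:
        if isinstance(r, Region):
            out.append(r)
        else:
            start, end, kind = r
            out.append(Region(int(start), int(end), str(kind)))
    return tuple(out)


def make_design(
    name: str,
    reference: str,
    regions: Sequence,
    cut_site: int,
    mut_substitutions: Iterable[Substitution],
    wtstar_substitutions: Iterable[Substitution],
    coding_frame_offset: int = 0,
) -> AmpliconDesign:
    """Build and validate an :class:`AmpliconDesign` in one step."""
    design = AmpliconDesign(
        name=name,
        reference=reference.upper(),
        regions=_as_regions(regions),
        cut_site=int(cut_site),
        mut_substitutions=frozenset(
            (int(p), str(r).upper(), str(a).upper()) for p, r, a in mut_substitutions
        ),
        wtstar_substitutions=frozenset(
            (int(p), str(r).upper(), str(a).upper()) for p, r, a in wtstar_substitutions
        ),
        coding_frame_offset=int(coding_frame_offset),
    )
    return validate_design(design)


def derive_splice_sites(design: AmpliconDesign) -> tuple[tuple[int, int], ...]:
    """Donor/acceptor dinucleotide intervals at each exon-intron junction.

    At an exon→intron junction the donor dinucleotide is the first two
    intronic bases; at an intron→exon junction the acceptor is the last
    two intronic bases. Junctions at the amplicon edge produce no site.
    """
    sites: list[tuple[int, int]] = []
    for left, right in zip(design.regions, design.regions[1:]):
        if left.kind == right.kind:
            continue
        boundary = left.end
        if right.kind == INTRON:  # donor: intron side, first 2 bases
            sites.append((boundary, min(boundary + SPLICE_SITE_WIDTH, len(design))))
        else:  # acceptor: intron side, last 2 bases
            sites.append((max(boundary - SPLICE_SITE_WIDTH, 0), boundary))
    return tuple(sites)


def validate_design(design: AmpliconDesign) -> AmpliconDesign:
    """Check all design invariants and derive splice sites.

    Raises
    ------
    RegionTilingError, SubstitutionRefMismatch, CutSiteOutOfRange, DesignError
    """
    ref = design.reference
    if not ref or set(ref) - VALID_BASES:
        raise DesignError("reference must be a non-empty ACGT string")

    expected_start = 0
    for region in design.regions:
        if region.start != expected_start:
            raise RegionTilingError(
                f"regions must tile the amplicon; got start {region.start}, "
                f"expected {expected_start}"
            )
        expected_start = region.end
    if expected_start != len(ref):
        raise RegionTilingError(
            f"regions end at {expected_start}, reference length {len(ref)}"
        )

    if not 0 <= design.cut_site <= len(ref):
        raise CutSiteOutOfRange(
            f"cut site {design.cut_site} outside [0,{len(ref)}]"
        )
    if not 0 <= design.coding_frame_offset <= 2:
        raise DesignError("coding_frame_offset must be 0, 1 or 2")

    for label, subs in (
        ("mut", design.mut_substitutions),
        ("wtstar", design.wtstar_substitutions),
    ):
        for pos, ref_base, alt_base in subs:
            if not 0 <= pos < len(ref):
                raise DesignError(f"{label} substitution at {pos} outside amplicon")
            if ref[pos] != ref_base:
                raise SubstitutionRefMismatch(
                    f"{label} substitution ref mismatch at {pos}: "
                    f"design says {ref_base}, reference has {ref[pos]}"
                )
            if alt_base == ref_base or alt_base not in VALID_BASES:
                raise DesignError(f"{label} substitution alt {alt_base!r} invalid")
            if abs(pos - design.cut_site) > HOMOLOGY_ARM_REACH:
                raise DesignError(
                    f"{label} substitution at {pos} beyond homology-arm reach "
                    f"({HOMOLOGY_ARM_REACH} bp) of cut site {design.cut_site}"
                )

    if design.mut_substitutions == design.wtstar_substitutions:
        raise DesignError("Mut and WT* substitution sets must differ")
    if not design.mut_substitutions or not design.wtstar_substitutions:
        raise DesignError("Mut and WT* substitution sets must be non-empty")

    return replace(design, splice_sites=derive_splice_sites(design))


def annotate_position(design: AmpliconDesign, pos: int) -> str:
    """Region label of one amplicon position.

    Returns ``exonic``, ``intronic`` or ``splice_site``; the splice-site
    dinucleotides take precedence over the underlying exon/intron label.
    """
    if not 0 <= pos < len(design):
        raise IndexError(f"position {pos} outside amplicon [0,{len(design)})")
    for start, end in design.splice_sites:
        if start <= pos < end:
            return SPLICE_SITE
    return EXONIC if design.region_at(pos).kind == EXON else INTRONIC


# -- serialization --------------------------------------------------------

def _subs_to_lists(subs: frozenset[Substitution]) -> list[list]:
    return [[p, r, a] for p, r, a in sorted(subs)]


def design_to_dict(design: AmpliconDesign) -> dict:
    return {
        "name": design.name,
        "reference": design.reference,
        "regions": [[r.start, r.end, r.kind] for r in design.regions],
        "coding_frame_offset": design.coding_frame_offset,
        "cut_site": design.cut_site,
        "mut_substitutions": _subs_to_lists(design.mut_substitutions),
        "wtstar_substitutions": _subs_to_lists(design.wtstar_substitutions),
    }


def design_from_dict(data: dict, base_dir: Path | None = None) -> AmpliconDesign:
    data = dict(data)
    if "reference_fasta" in data and "reference" not in data:
        from Bio import SeqIO

        path = Path(data.pop("reference_fasta"))
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        record = next(SeqIO.parse(str(path), "fasta"))
        data["reference"] = str(record.seq).upper()
    return make_design(
        name=data["name"],
        reference=data["reference"],
        regions=data["regions"],
        cut_site=data["cut_site"],
        mut_substitutions=[tuple(s) for s in data["mut_substitutions"]],
        wtstar_substitutions=[tuple(s) for s in data["wtstar_substitutions"]],
        coding_frame_offset=data.get("coding_frame_offset", 0),
    )


def save_design(design: AmpliconDesign, path: str | Path) -> None:
    path = Path(path)
    data = design_to_dict(design)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def example_design(intron_guide: bool = False, seed: int = 17) -> AmpliconDesign:
    """A 240-bp demo amplicon: one exon followed by one intron.

    The exon-guide variant cuts inside the exon near recurrent missense
    positions; the intron-guide (single-allele editing) variant cuts
    just inside the intron so imperfect repair yields noncoding InDels
    while the templates still edit the exonic site.

    Each template installs two base changes (the edit of interest plus
    a PAM/seed-blocking change), as knock-in donors do in practice;
    this also means a single sequencing error cannot convert one
    template read into the other or into a false knock-in call.
    """
    import numpy as _np

    rng = _np.random.default_rng(seed)
    reference = "".join(rng.choice(list("ACGT"), size=240))
    regions = [(0, 120, EXON), (120, 240, INTRON)]
    if intron_guide:
        cut = 126
        mut_positions, wts_positions = (109, 110), (103, 104)
    else:
        cut = 100
        mut_positions, wts_positions = (97, 98), (91, 92)

    def _sub(pos):
        ref_base = reference[pos]
        alt = next(b for b in "ACGT" if b != ref_base)
        return (pos, ref_base, alt)

    return make_design(
        name="demo-intron" if intron_guide else "demo-exon",
        reference=reference,
        regions=regions,
        cut_site=cut,
        mut_substitutions=[_sub(p) for p in mut_positions],
        wtstar_substitutions=[_sub(p) for p in wts_positions],
        coding_frame_offset=0,
    )


def load_design(path: str | Path) -> AmpliconDesign:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return design_from_dict(data, base_dir=path.parent)
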