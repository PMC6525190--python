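"""Amplicon loci, guide geometry, quantification windows and ssODN donor design.

An :class:`AmpliconLocus` ties a reference amplicon to the 20-nt protospacer
matched by an sgRNA, its NGG PAM, the expected SpCas9 cut/nick site (the blunt
cut 3 bp 5' of the PAM, between protospacer positions 17 and 18) and the 10-bp
quantification window centred on that site.  Donor templates are 100-mer
single-stranded oligonucleotides (ssODNs) carrying a target SNP inside the
protospacer, optionally together with a PAM-blocking mutation (e.g. TGG->TTT)
that prevents re-cutting of the edited allele.

Protospacer coordinates follow the 1-25 convention in which the PAM occupies
positions 21-23 (position 20 abuts the PAM); internally every coordinate is
0-based, half-open on the reference top strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

__all__ = [
    "AmpliconLocus",
    "DonorTemplate",
    "EnzymeVariant",
    "ENZYMES",
    "LocusError",
    "LocusNotFoundError",
    "AmbiguousLocusError",
    "revcomp",
    "locate_protospacer",
    "quantification_window",
    "ps_coord_to_ref",
    "ref_to_ps_coord",
    "design_donor",
    "positional_series",
    "apply_hdr",
    "rebase_donor",
    "trim_to_read_length",
    "DEFAULT_TRANSVERSION",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default substitution used when a donor series does not specify alleles:
#: a transversion, guaranteed to differ from the reference base.
DEFAULT_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}

# IUPAC nucleotide codes -> the set of bases they match.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: blunt SpCas9 cut between protospacer positions 17 and 18 (3 bp 5' of PAM)
CUT_OFFSET = 17


class LocusError(ValueError):
    """Base class for locus definition problems."""


class LocusNotFoundError(LocusError):
    pass


class AmbiguousLocusError(LocusError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def _matches_iupac(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(seq, pattern)
    )


@dataclass(frozen=True)
class AmpliconLocus:
    """A reference amplicon annotated with guide geometry.

    ``protospacer_start`` is the 0-based offset of the protospacer on the
    strand on which protospacer+PAM read 5'->3' (the reference itself for
    '+', its reverse complement for '-').  ``cut_site`` and ``window`` are
    always inter-base / half-open coordinates on the reference top strand.
    """

    name: str
    reference: str
    protospacer: str
    protospacer_start: int
    strand: str  # '+' or '-'
    pam: str
    cut_site: int
    window: tuple[int, int]

    @property
    def ps_ref_interval(self) -> tuple[int, int]:
        """Half-open reference-frame interval occupied by the protospacer."""
        if self.strand == "+":
            return self.protospacer_start, self.protospacer_start + PROTOSPACER_LEN
        start = len(self.reference) - self.protospacer_start - PROTOSPACER_LEN
        return start, start + PROTOSPACER_LEN


@dataclass(frozen=True)
class EnzymeVariant:
    """Which DNA strand(s) a Cas9 variant cleaves.

    D10A-derived variants (including every RDN fusion) nick only the guide
    RNA-paired strand; H840A nicks the opposite (displaced) strand; dCas9
    cleaves neither.  All nicks/cuts are windowed at the same reference
    coordinate (the blunt-cut position).
    """

    name: str
    cuts_guide_paired_strand: bool
    cuts_opposite_strand: bool


ENZYMES: dict[str, EnzymeVariant] = {
    "Cas9": EnzymeVariant("Cas9", True, True),
    "Cas9_D10A": EnzymeVariant("Cas9_D10A", True, False),
    "Cas9_H840A": EnzymeVariant("Cas9_H840A", False, True),
    "dCas9": EnzymeVariant("dCas9", False, False),
    "RDN": EnzymeVariant("RDN", True, False),
    "RDN_mutant": EnzymeVariant("RDN_mutant", True, False),
}


@dataclass(frozen=True)
class DonorTemplate:
    """A single-stranded oligonucleotide donor (default 100-mer).

    ``target_snps`` and ``pam_block`` are reference-frame substitutions
    ``(position, reference allele, donor allele)``; ``span`` is the half-open
    reference interval the donor covers.  ``sequence`` is the oligo as
    synthesized: for a 'forward' donor it reads in the same sense as the
    sgRNA, for 'reverse' it is the reverse complement.
    """

    sequence: str
    orientation: str  # 'forward' or 'reverse'
    target_snps: tuple[tuple[int, str, str], ...]
    pam_block: tuple[tuple[int, str, str], ...] = ()
    span: tuple[int, int] = (0, 0)
    protospacer_position_of_edit: Optional[int] = None
    locus_name: str = ""
    name: str = ""

    @property
    def edited_positions(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.target_snps + self.pam_block)


def locate_protospacer(
    reference: str,
    protospacer: str,
    pam_pattern: str = "NGG",
    name: str = "locus",
    half_width: int = 5,
) -> AmpliconLocus:
    """Find the unique protospacer+PAM occurrence and annotate the locus.

    Searches both strands for the 20-nt protospacer immediately followed by
    a PAM matching ``pam_pattern``; exactly one match is required.

    Raises
    ------
    LocusNotFoundError / AmbiguousLocusError
        With a message naming ``name`` when the protospacer+PAM is absent
        or occurs more than once across both strands.
    """
    reference = reference.upper()
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise LocusError(
            f"{name}: protospacer must be {PROTOSPACER_LEN} nt, got {len(protospacer)}"
        )

    hits: list[tuple[str, int]] = []  # (strand, offset on that strand's sequence)
    for strand, seq in (("+", reference), ("-", revcomp(reference))):
        start = 0
        while True:
            i = seq.find(protospacer, start)
            if i < 0:
                break
            pam = seq[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + PAM_LEN]
            if _matches_iupac(pam, pam_pattern):
                hits.append((strand, i))
            start = i + 1

    if not hits:
        raise LocusNotFoundError(
            f"{name}: protospacer+{pam_pattern} not found on either strand"
        )
    if len(hits) > 1:
        raise AmbiguousLocusError(
            f"{name}: protospacer+{pam_pattern} found {len(hits)} times; "
            "amplicon must contain a unique target site"
        )

    strand, offset = hits[0]
    seq = reference if strand == "+" else revcomp(reference)
    pam = seq[offset + PROTOSPACER_LEN : offset + PROTOSPACER_LEN + PAM_LEN]
    if strand == "+":
        cut_site = offset + CUT_OFFSET
    else:
        # protospacer occupies [L-offset-20, L-offset) on the reference;
        # the cut sits CUT_OFFSET into the protospacer reading 5'->3' on '-'.
        cut_site = len(reference) - offset - CUT_OFFSET

    locus = AmpliconLocus(
        name=name,
        reference=reference,
        protospacer=protospacer,
        protospacer_start=offset,
        strand=strand,
        pam=pam,
        cut_site=cut_site,
        window=(0, 0),
    )
    return replace(locus, window=quantification_window(locus, half_width))


def quantification_window(locus: AmpliconLocus, half_width: int = 5) -> tuple[int, int]:
    """Half-open window ``[cut_site - half_width, cut_site + half_width)``.

    The default ``half_width`` of 5 gives the 10-bp indel quantification
    window around the expected cleavage site.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    start = locus.cut_site - half_width
    end = locus.cut_site + half_width
    if start < 0 or end > len(locus.reference):
        raise LocusError(
            f"{locus.name}: quantification window [{start}, {end}) extends past "
            f"the amplicon (length {len(locus.reference)}); amplicon too short"
        )
    return (start, end)


def ps_coord_to_ref(locus: AmpliconLocus, position: int) -> int:
    """Map a protospacer coordinate (1-25, PAM = 21-23) to a reference position."""
    if not 1 <= position <= 25:
        raise ValueError(f"protospacer position must be in 1..25, got {position}")
    ps_start, ps_end = locus.ps_ref_interval
    if locus.strand == "+":
        ref_pos = ps_start + position - 1
    else:
        ref_pos = ps_end - position
    if not 0 <= ref_pos < len(locus.reference):
        raise LocusError(
            f"{locus.name}: protospacer position {position} maps outside the amplicon"
        )
    return ref_pos


def ref_to_ps_coord(locus: AmpliconLocus, ref_pos: int) -> int:
    """Inverse of :func:`ps_coord_to_ref` (valid within positions 1-25)."""
    ps_start, ps_end = locus.ps_ref_interval
    if locus.strand == "+":
        position = ref_pos - ps_start + 1
    else:
        position = ps_end - ref_pos
    if not 1 <= position <= 25:
        raise ValueError(f"reference position {ref_pos} outside protospacer coords 1..25")
    return position


def _strand_base(locus: AmpliconLocus, base: str) -> str:
    """Convert a base given in protospacer-strand sense to reference-frame."""
    return base if locus.strand == "+" else base.translate(_COMPLEMENT)


def _pam_block_substitutions(
    locus: AmpliconLocus, replacement: str
) -> tuple[tuple[int, str, str], ...]:
    """Reference-frame substitutions realizing a PAM replacement (e.g. TGG->TTT).

    Only the PAM positions where the replacement actually differs from the
    native PAM are recorded.
    """
    if len(replacement) != PAM_LEN:
        raise ValueError(f"PAM replacement must be {PAM_LEN} nt, got {replacement!r}")
    replacement = replacement.upper()
    if replacement == locus.pam:
        warnings.warn(
            f"{locus.name}: PAM replacement {replacement} is identical to the "
            "native PAM; no blocking mutation introduced",
            stacklevel=3,
        )
        return ()
    subs = []
    for t in range(PAM_LEN):
        if replacement[t] == locus.pam[t]:
            continue
        ref_pos = ps_coord_to_ref(locus, 21 + t)
        subs.append(
            (ref_pos, locus.reference[ref_pos], _strand_base(locus, replacement[t]))
        )
    return tuple(subs)


def design_donor(
    locus: AmpliconLocus,
    edit: tuple[int, str],
    length: int = 100,
    pam_block: Optional[str] = None,
    orientation: str = "forward",
    name: str = "",
) -> DonorTemplate:
    """Design an ssODN donor carrying one target SNP, per the 100-mer convention.

    Parameters
    ----------
    edit
        ``(protospacer position 1-25, donor allele)``; the allele is given in
        the sgRNA (protospacer-strand) sense.
    pam_block
        Optional 3-nt PAM replacement in protospacer-strand sense (e.g.
        ``"TTT"`` to block a TGG PAM); a replacement equal to the native PAM
        warns and is dropped.
    orientation
        ``forward`` = same sense as the sgRNA; ``reverse`` returns the
        reverse complement oligo.

    The donor is centred on the protospacer midpoint, truncated only by the
    amplicon ends, and differs from the reference exclusively at the target
    SNP and PAM-block positions.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    if length > len(locus.reference):
        raise LocusError(
            f"{locus.name}: donor length {length} exceeds amplicon length "
            f"{len(locus.reference)}"
        )
    position, allele = edit
    allele = allele.upper()
    ref_pos = ps_coord_to_ref(locus, position)
    ref_allele = locus.reference[ref_pos]
    donor_allele = _strand_base(locus, allele)
    if donor_allele == ref_allele:
        raise ValueError(
            f"{locus.name}: donor allele {allele} at protospacer position "
            f"{position} equals the reference base; not an edit"
        )
    target_snps = ((ref_pos, ref_allele, donor_allele),)

    block_subs = _pam_block_substitutions(locus, pam_block) if pam_block else ()
    # an edit inside the PAM takes precedence over the block at that position
    block_subs = tuple(s for s in block_subs if s[0] != ref_pos)

    ps_start, ps_end = locus.ps_ref_interval
    mid = (ps_start + ps_end) // 2
    start = mid - length // 2
    start = max(0, min(start, len(locus.reference) - length))
    end = start + length

    subs = {p: d for p, _, d in target_snps + block_subs}
    for p in subs:
        if not start <= p < end:
            raise LocusError(
                f"{locus.name}: edited position {p} falls outside the donor "
                f"span [{start}, {end})"
            )
    seq = "".join(subs.get(i, locus.reference[i]) for i in range(start, end))
    if locus.strand == "-":
        # 'forward' means sgRNA sense, which is the reference bottom strand here
        seq = revcomp(seq)
    if orientation == "reverse":
        seq = revcomp(seq)

    return DonorTemplate(
        sequence=seq,
        orientation=orientation,
        target_snps=target_snps,
        pam_block=block_subs,
        span=(start, end),
        protospacer_position_of_edit=position,
        locus_name=locus.name,
        name=name or f"{locus.name}_pos{position}{'_pamblock' if block_subs else ''}",
    )


def positional_series(
    locus: AmpliconLocus,
    positions: Sequence[int],
    pam_block: Optional[str] = None,
    allele_for: Optional[Callable[[str], str]] = None,
    length: int = 100,
    orientation: str = "forward",
) -> list[DonorTemplate]:
    """One donor per protospacer position; two per position when a PAM block is given.

    Emulates a positional SNP series scanning protospacer positions (1-25,
    PAM = 21-23).  ``allele_for`` maps the reference base (protospacer-strand
    sense) to the donor allele; the default is a fixed transversion so the
    donor base always differs from the reference.  With ``pam_block``, each
    position yields the non-blocking donor followed by the PAM-blocking one
    (the two donor sets used for such series).
    """
    allele_for = allele_for or (lambda ref_base: DEFAULT_TRANSVERSION[ref_base])
    donors: list[DonorTemplate] = []
    for position in positions:
        ref_pos = ps_coord_to_ref(locus, position)
        ref_base = locus.reference[ref_pos]
        if locus.strand == "-":
            ref_base = ref_base.translate(_COMPLEMENT)
        allele = allele_for(ref_base)
        donors.append(
            design_donor(locus, (position, allele), length=length, orientation=orientation)
        )
        if pam_block:
            donors.append(
                design_donor(
                    locus,
                    (position, allele),
                    length=length,
                    pam_block=pam_block,
                    orientation=orientation,
                )
            )
    return donors


def apply_hdr(reference: str, donor: DonorTemplate) -> str:
    """Substitute all donor target SNPs (and PAM-block bases) into the
    reference; length is unchanged."""
    seq = list(reference)
    for pos, _ref, alt in donor.target_snps + donor.pam_block:
        seq[pos] = alt
    return "".join(seq)


def rebase_donor(
    donor: DonorTemplate, locus: AmpliconLocus, eff: AmpliconLocus
) -> DonorTemplate:
    """Re-express a donor's reference coordinates on a trimmed amplicon."""
    if eff.reference == locus.reference:
        return donor
    shift = locus.reference.find(eff.reference)
    if shift < 0:
        raise LocusError(
            f"{locus.name}: effective amplicon is not a subsequence of the locus"
        )

    def move(subs: tuple[tuple[int, str, str], ...]) -> tuple[tuple[int, str, str], ...]:
        return tuple((p - shift, r, a) for p, r, a in subs)

    return replace(
        donor,
        target_snps=move(donor.target_snps),
        pam_block=move(donor.pam_block),
        span=(donor.span[0] - shift, donor.span[1] - shift),
    )


def trim_to_read_length(
    locus: AmpliconLocus, max_len: int = 270, target_len: int = 250
) -> AmpliconLocus:
    """Trim an over-long amplicon to single-end read length around the window.

    Sequencing reads span 230-270 nt; when the reference amplicon is longer
    than ``max_len`` the effective amplicon is the ``target_len`` subsequence
    centred on the quantification window (clamped to the amplicon ends), and
    all coordinates are shifted accordingly.  Loci already within read length
    are returned unchanged.
    """
    ref = locus.reference
    if len(ref) <= max_len:
        return locus
    w_start, w_end = locus.window
    mid = (w_start + w_end) // 2
    start = max(0, min(mid - target_len // 2, len(ref) - target_len))
    end = start + target_len
    ps_start, ps_end = locus.ps_ref_interval
    if ps_start - PAM_LEN < start or ps_end + PAM_LEN > end:
        raise LocusError(
            f"{locus.name}: cannot trim to {target_len} nt without losing the "
            "protospacer/PAM"
        )
    new_ref = ref[start:end]
    if locus.strand == "+":
        new_offset = locus.protospacer_start - start
    else:
        new_offset = locus.protospacer_start - (len(ref) - end)
    return AmpliconLocus(
        name=locus.name,
        reference=new_ref,
        protospacer=locus.protospacer,
        protospacer_start=new_offset,
        strand=locus.strand,
        pam=locus.pam,
        cut_site=locus.cut_site - start,
        window=(w_start - start, w_end - start),
    )
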