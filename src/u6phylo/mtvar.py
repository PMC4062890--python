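"""rCRS-relative mtDNA variants and haplotype profiles.

Every mutation is expressed against the revised Cambridge Reference
Sequence (rCRS, 16,569 bp) in the notation conventional for control-region
and complete-genome haplotype reports:

* ``16189``   bare digits — a transition;
* ``794A``    position + base — a transversion to that base;
* ``455.1T``  position + ``.index`` + base — an insertion after the position;
* ``960d``    position + ``d`` — a deletion;
* ``750!``    trailing ``!`` — a back-mutation (reversion to the ancestral
  state at that position);
* ``146Y``    position + IUPAC ambiguity code — a heteroplasmic record,
  parsed but flagged and excluded from distances by default.

A :class:`HaplotypeProfile` is a set of variants together with the rCRS
interval(s) actually sequenced (a complete genome, or just HVS-I), so that
partial sequences can be compared and classified range-aware.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "RCRS_LENGTH",
    "WHOLE_GENOME",
    "HVR1",
    "VariantKind",
    "Variant",
    "VariantParseError",
    "HaplotypeProfile",
    "parse_variant",
    "format_variant",
    "parse_profile",
    "read_motif_file",
    "write_motif_file",
    "profiles_from_alignment",
    "restrict_profile",
    "profile_distance",
    "is_hypervariable",
]

RCRS_LENGTH = 16569
WHOLE_GENOME: tuple[tuple[int, int], ...] = ((1, RCRS_LENGTH),)
#: Hypervariable segment I; conventional bounds used for partial typing.
HVR1: tuple[tuple[int, int], ...] = ((16024, 16365),)

_BASES = frozenset("ACGT")
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")

#: Positions/tracts excluded from classification and diversity by default:
#: the 16519 hotspot and the homopolymeric cytosine tracts around 310 and
#: 16189 whose length variants (insertions, 16183C-type transversions) are
#: not phylogenetically stable.
_HYPERVARIABLE_POSITIONS = frozenset({16519})
_POLY_C_TRACTS = ((302, 316), (16182, 16194))

_TOKEN_RE = re.compile(r"(\d+)(?:\.(\d+))?([A-Za-z]?)(!?)")


class VariantKind(str, Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"
    BACK_MUTATION = "back_mutation"


class VariantParseError(ValueError):
    """Raised for a token that does not match the variant grammar."""


@dataclass(frozen=True, order=True)
class Variant:
    """One rCRS-relative mutation event.

    Parameters
    ----------
    position
        1-based rCRS coordinate, 1..16569.
    kind
        Event type. ``BACK_MUTATION`` marks a reversion to the ancestral
        state (``750!`` notation).
    derived_base
        Required for transversions and insertions, absent otherwise.
    insertion_index
        The ``.1`` in ``455.1T``; insertions only.
    iupac_code
        Ambiguity letter for heteroplasmic records (``146Y``); such records
        are flagged and excluded from distances/classification by default.
    """

    position: int
    kind: VariantKind = VariantKind.TRANSITION
    derived_base: str | None = None
    insertion_index: int | None = None
    iupac_code: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise VariantParseError(
                f"position {self.position} outside rCRS coordinates 1..{RCRS_LENGTH}"
            )
        if self.kind in (VariantKind.TRANSVERSION, VariantKind.INSERTION):
            if self.derived_base not in _BASES:
                raise VariantParseError(
                    f"{self.kind.value} at {self.position} requires a derived base in ACGT"
                )
        elif self.kind in (VariantKind.TRANSITION, VariantKind.DELETION):
            if self.derived_base is not None:
                raise VariantParseError(
                    f"{self.kind.value} at {self.position} must not carry a derived base"
                )
        if self.kind is VariantKind.INSERTION and not self.insertion_index:
            raise VariantParseError(f"insertion at {self.position} requires an index")
        if self.kind is not VariantKind.INSERTION and self.insertion_index:
            raise VariantParseError(f"{self.kind.value} cannot carry an insertion index")

    @property
    def heteroplasmic(self) -> bool:
        return self.iupac_code is not None

    def __str__(self) -> str:
        return format_variant(self)


def parse_variant(token: str) -> Variant:
    """Parse one variant token (``794A``, ``455.1T``, ``960d``, ``750!``...).

    Raises :class:`VariantParseError` naming the token on any malformed
    input (non-numeric position, out-of-range coordinate, unknown letter).
    """
    m = _TOKEN_RE.fullmatch(token.strip())
    if m is None:
        raise VariantParseError(f"malformed variant token {token!r}")
    pos_s, idx_s, letter, bang = m.groups()
    position = int(pos_s)
    if not 1 <= position <= RCRS_LENGTH:
        raise VariantParseError(f"token {token!r}: position outside 1..{RCRS_LENGTH}")
    back = bang == "!"
    try:
        if idx_s is not None:
            if letter.upper() not in _BASES:
                raise VariantParseError(
                    f"token {token!r}: insertion requires a base in ACGT"
                )
            return Variant(position, VariantKind.INSERTION, letter.upper(), int(idx_s))
        if letter == "":
            kind = VariantKind.BACK_MUTATION if back else VariantKind.TRANSITION
            return Variant(position, kind)
        if letter == "d":
            return Variant(position, VariantKind.DELETION)
        if letter in _BASES:
            kind = VariantKind.BACK_MUTATION if back else VariantKind.TRANSVERSION
            return Variant(position, kind, letter)
        if letter.upper() in _IUPAC_AMBIGUOUS:
            # heteroplasmy record, e.g. 146Y
            return Variant(position, VariantKind.TRANSITION, iupac_code=letter.upper())
    except VariantParseError:
        raise
    raise VariantParseError(f"token {token!r}: unknown state letter {letter!r}")


def format_variant(v: Variant) -> str:
    """Canonical token for a variant; inverse of :func:`parse_variant`."""
    if v.kind is VariantKind.INSERTION:
        return f"{v.position}.{v.insertion_index}{v.derived_base}"
    if v.kind is VariantKind.DELETION:
        return f"{v.position}d"
    if v.iupac_code is not None:
        return f"{v.position}{v.iupac_code}"
    base = v.derived_base or ""
    bang = "!" if v.kind is VariantKind.BACK_MUTATION else ""
    return f"{v.position}{base}{bang}"


def is_hypervariable(v: Variant) -> bool:
    """True for the 16519 hotspot and poly-C tract length variants.

    These parse normally but are excluded from classification and pi
    computations under the default site policy.
    """
    if v.position in _HYPERVARIABLE_POSITIONS:
        return True
    for lo, hi in _POLY_C_TRACTS:
        if lo <= v.position <= hi:
            if v.kind is VariantKind.INSERTION:
                return True
            if v.kind is VariantKind.TRANSVERSION and v.derived_base == "C":
                return True  # 16183C-type tract extension
    return False


# ---------------------------------------------------------------------------
# coordinate intervals

def _normalize_intervals(
    intervals: Iterable[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in ivs:
        if a > b or a < 1 or b > RCRS_LENGTH:
            raise ValueError(f"bad rCRS interval {a}..{b}")
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def _in_intervals(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(a <= pos <= b for a, b in intervals)


def _intersect_intervals(
    xs: Sequence[tuple[int, int]], ys: Sequence[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    out = []
    for a, b in xs:
        for c, d in ys:
            lo, hi = max(a, c), min(b, d)
            if lo <= hi:
                out.append((lo, hi))
    return tuple(out)


# ---------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class HaplotypeProfile:
    """A set of variants plus the rCRS interval(s) actually covered."""

    variants: frozenset[Variant] = frozenset()
    covered_range: tuple[tuple[int, int], ...] = WHOLE_GENOME
    sample_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", frozenset(self.variants))
        object.__setattr__(
            self, "covered_range", _normalize_intervals(self.covered_range)
        )
        for v in self.variants:
            if not _in_intervals(v.position, self.covered_range):
                raise ValueError(
                    f"variant {v} outside covered range {self.covered_range}"
                )

    @classmethod
    def from_tokens(
        cls,
        tokens: Iterable[str],
        covered_range: Sequence[tuple[int, int]] = WHOLE_GENOME,
        sample_id: str | None = None,
    ) -> "HaplotypeProfile":
        return cls(
            frozenset(parse_variant(t) for t in tokens),
            tuple(covered_range),
            sample_id,
        )

    def covers(self, position: int) -> bool:
        return _in_intervals(position, self.covered_range)

    def positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.variants)

    def add(self, v: Variant) -> "HaplotypeProfile":
        """Return a profile with ``v`` added (set semantics: no-op if present)."""
        return replace(self, variants=self.variants | {v})

    def tokens(self) -> list[str]:
        return [format_variant(v) for v in sorted(self.variants)]

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, item: Variant | str) -> bool:
        if isinstance(item, str):
            item = parse_variant(item)
        return item in self.variants


def parse_profile(
    line: str,
    covered_range: Sequence[tuple[int, int]] = WHOLE_GENOME,
    with_id: bool | None = None,
) -> HaplotypeProfile:
    """Parse one whitespace-separated motif line, optional leading sample ID.

    When ``with_id`` is None the first field is treated as an ID iff it does
    not parse as a variant token.
    """
    fields = line.split()
    sample_id = None
    if fields and with_id is not False:
        try:
            parse_variant(fields[0])
            explicit_id = False
        except VariantParseError:
            explicit_id = True
        if with_id or explicit_id:
            sample_id = fields[0]
            fields = fields[1:]
    return HaplotypeProfile.from_tokens(fields, covered_range, sample_id)


def read_motif_file(
    path, covered_range: Sequence[tuple[int, int]] = WHOLE_GENOME
) -> list[HaplotypeProfile]:
    """Read an EMPOP-like motif file: one haplotype per line, ``#`` comments."""
    profiles = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                profiles.append(parse_profile(line, covered_range))
            except (VariantParseError, ValueError) as exc:
                raise VariantParseError(f"{path}:{lineno}: {exc}") from exc
    return profiles


def write_motif_file(path, profiles: Iterable[HaplotypeProfile]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(profiles, 1):
            sid = p.sample_id or f"S{i}"
            fh.write(sid + "\t" + " ".join(p.tokens()) + "\n")


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def profiles_from_alignment(path, reference: str, offset: int = 16023):
    """Call variants from pre-aligned FASTA fragments at a fixed rCRS offset.

    ``reference`` is the rCRS segment the fragments are aligned to;
    rCRS position of column i (0-based) is ``offset + 1 + i``. Substitutions
    become transitions/transversions by purine/pyrimidine class, ``-``
    becomes a deletion, IUPAC ambiguity codes become flagged heteroplasmy
    records. No alignment is performed here.
    """
    from Bio import SeqIO

    reference = reference.upper()
    covered = ((offset + 1, offset + len(reference)),)
    profiles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) != len(reference):
            raise ValueError(
                f"{rec.id}: fragment length {len(seq)} != reference {len(reference)}"
            )
        variants = set()
        for i, (ref_b, obs_b) in enumerate(zip(reference, seq)):
            if obs_b == ref_b or obs_b == "N":
                continue
            pos = offset + 1 + i
            if obs_b == "-":
                variants.add(Variant(pos, VariantKind.DELETION))
            elif obs_b in _BASES:
                if (ref_b, obs_b) in _TRANSITIONS:
                    variants.add(Variant(pos, VariantKind.TRANSITION))
                else:
                    variants.add(Variant(pos, VariantKind.TRANSVERSION, obs_b))
            elif obs_b in _IUPAC_AMBIGUOUS:
                variants.add(Variant(pos, VariantKind.TRANSITION, iupac_code=obs_b))
            else:
                raise ValueError(f"{rec.id}: unexpected state {obs_b!r} at {pos}")
        profiles.append(HaplotypeProfile(frozenset(variants), covered, rec.id))
    return profiles


def restrict_profile(
    profile: HaplotypeProfile, region: Sequence[tuple[int, int]]
) -> HaplotypeProfile:
    """Restrict a profile to ``region`` (variants and covered range).

    An empty intersection yields an empty profile, not an error.
    """
    region = _normalize_intervals(region)
    shared = _intersect_intervals(profile.covered_range, region)
    kept = frozenset(v for v in profile.variants if _in_intervals(v.position, shared))
    return HaplotypeProfile(kept, shared, profile.sample_id)


def _scored_variants(
    p: HaplotypeProfile,
    shared: Sequence[tuple[int, int]],
    include_hypervariable: bool,
    include_heteroplasmic: bool,
) -> frozenset[Variant]:
    return frozenset(
        v
        for v in p.variants
        if _in_intervals(v.position, shared)
        and (include_hypervariable or not is_hypervariable(v))
        and (include_heteroplasmic or not v.heteroplasmic)
    )


def profile_distance(
    a: HaplotypeProfile,
    b: HaplotypeProfile,
    *,
    include_hypervariable: bool = False,
    include_heteroplasmic: bool = False,
) -> int:
    """Number of differing variants between two profiles (symmetric difference).

    Profiles with different covered ranges are compared on the intersection.
    Hypervariable sites (16519, poly-C length variants) and heteroplasmic
    records are excluded by default. This is the pairwise-difference
    substrate of the pi diversity statistic and is a metric on profiles with
    a common range.
    """
    shared = _intersect_intervals(a.covered_range, b.covered_range)
    va = _scored_variants(a, shared, include_hypervariable, include_heteroplasmic)
    vb = _scored_variants(b, shared, include_hypervariable, include_heteroplasmic)
    return len(va ^ vb)
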