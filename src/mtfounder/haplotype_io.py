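"""Haplotype and metadata I/O, variant notation, masking and motif calls.

Mitochondrial haplotypes are represented as sets of :class:`Mutation`
objects relative to the rCRS coordinate system, using the field's
conventional notation: ``16247G`` (substitution), ``315.1C`` (insertion,
".1"-style suffix), ``522d`` (deletion).  The module also implements the
position mask and character-weighting scheme used when building
haplotype networks: a set of notoriously unstable or artefact-prone
positions is excluded outright, and nine well-known hypervariable
hotspot positions are down-weighted from 10 to 7.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .reference import MT_LENGTH, reference_base, transition_partner

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_AMBIGUOUS = set("NRYWSKMBDHV?X")

TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"


class VariantParseError(ValueError):
    """A variant token does not match the ``<pos>[.<idx>]<base|d>`` grammar."""


class JoinError(ValueError):
    """Sequence records and metadata rows could not be joined one-to-one."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single variant relative to the reference.

    ``derived_allele`` is a single upper-case base for substitutions and
    insertions, or ``"d"`` for deletions.  ``insertion_index`` is the
    1-based ``.N`` suffix and is present iff ``kind == "insertion"``.
    """

    position: int
    derived_allele: str
    kind: str
    insertion_index: int | None = None

    def __post_init__(self):
        if not 1 <= self.position <= MT_LENGTH:
            raise ValueError(f"position {self.position} outside 1..{MT_LENGTH}")
        if (self.insertion_index is not None) != (self.kind == INSERTION):
            raise ValueError("insertion_index present iff kind=insertion")

    @property
    def is_substitution(self) -> bool:
        return self.kind in (TRANSITION, TRANSVERSION)

    @property
    def site(self) -> tuple[int, int | None]:
        """(position, insertion_index) — the locus this variant occupies."""
        return (self.position, self.insertion_index)

    def token(self) -> str:
        if self.kind == INSERTION:
            return f"{self.position}.{self.insertion_index}{self.derived_allele}"
        if self.kind == DELETION:
            return f"{self.position}d"
        return f"{self.position}{self.derived_allele}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


@dataclass(frozen=True)
class MitoHaplotype:
    """One sample's variant profile plus geographic metadata."""

    sample_id: str
    variants: frozenset[Mutation]
    island: str = ""
    region: str = ""
    lat: float = float("nan")
    lon: float = float("nan")
    source_flags: tuple[str, ...] = ()

    def __post_init__(self):
        sites = [m.site for m in self.variants]
        if len(sites) != len(set(sites)):
            raise ValueError(
                f"{self.sample_id}: two variants share a (position, insertion_index) site"
            )

    @property
    def substitutions(self) -> frozenset[Mutation]:
        return frozenset(m for m in self.variants if m.is_substitution)

    def with_variants(self, variants: Iterable[Mutation]) -> "MitoHaplotype":
        return replace(self, variants=frozenset(variants))


_TOKEN_RE = re.compile(
    r"^\s*(\d{1,3}(?:,\d{3})*|\d+)(?:\.(\d+))?\s*([ACGTacgt]|[dD])\s*$"
)


def parse_variant_token(token: str, reference: str | None = None) -> Mutation:
    """Parse one variant token (``"16247G"``, ``"16,247 G"``, ``"315.1C"``,
    ``"522d"``) into a :class:`Mutation`.

    Substitutions are classified as transition/transversion against the
    packaged reference (or an explicit *reference* sequence).
    """
    m = _TOKEN_RE.match(token)
    if not m:
        raise VariantParseError(f"malformed variant token: {token!r}")
    position = int(m.group(1).replace(",", ""))
    if not 1 <= position <= MT_LENGTH:
        raise VariantParseError(f"position {position} outside 1..{MT_LENGTH} in {token!r}")
    idx = m.group(2)
    allele = m.group(3).upper() if m.group(3) not in ("d", "D") else "d"
    if idx is not None:
        if allele == "d":
            raise VariantParseError(f"insertion token cannot delete: {token!r}")
        return Mutation(position, allele, INSERTION, insertion_index=int(idx))
    if allele == "d":
        return Mutation(position, "d", DELETION)
    ref = reference_base(position, reference)
    if allele == ref:
        raise VariantParseError(f"{token!r}: derived allele equals reference base {ref}")
    if {allele, ref} <= _PURINES or {allele, ref} <= _PYRIMIDINES:
        kind = TRANSITION
    else:
        kind = TRANSVERSION
    return Mutation(position, allele, kind)


def parse_profile(tokens: Iterable[str] | str, reference: str | None = None) -> frozenset[Mutation]:
    """Parse a whitespace-separated variant profile into a mutation set."""
    if isinstance(tokens, str):
        tokens = tokens.split()
    return frozenset(parse_variant_token(t, reference) for t in tokens)


# ---------------------------------------------------------------------------
# Position mask and weights
# ---------------------------------------------------------------------------

#: Mask used when building networks: mixes ranges, allele-specific tokens
#: and the 3107 placeholder, following the Network-software convention.
DEFAULT_EXCLUDED_TOKENS = (
    "308-315",
    "310C",
    "3107N",
    "515-522",
    "16182C",
    "16183C",
    "16192C",
    "16518T",
    "16519C",
)

#: Hypervariable hotspot positions down-weighted (10 -> 7) in networks.
DEFAULT_DOWNWEIGHTED = frozenset(
    {146, 150, 152, 195, 16093, 16129, 16189, 16311, 16362}
)

_RANGE_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")
_ALLELE_RE = re.compile(r"^(\d+)\s*([ACGTN])$", re.IGNORECASE)


@dataclass
class PositionConfig:
    """Excluded positions, down-weighted hotspots and per-position rates."""

    excluded_ranges: tuple[tuple[int, int], ...] = ()
    excluded_alleles: frozenset[tuple[int, str]] = frozenset()
    excluded_positions: frozenset[int] = frozenset()
    downweighted: frozenset[int] = DEFAULT_DOWNWEIGHTED
    default_weight: float = 10.0
    reduced_weight: float = 7.0
    per_position_rate: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.reduced_weight >= self.default_weight:
            raise ValueError("reduced_weight must be < default_weight")
        overlap = self.downweighted & self.excluded_positions
        overlap |= {
            p for p in self.downweighted
            for lo, hi in self.excluded_ranges if lo <= p <= hi
        }
        if overlap:
            raise ValueError(f"downweighted positions also excluded: {sorted(overlap)}")

    @classmethod
    def default(cls) -> "PositionConfig":
        return cls.from_tokens(DEFAULT_EXCLUDED_TOKENS)

    @classmethod
    def from_tokens(cls, tokens: Sequence[str], **kwargs) -> "PositionConfig":
        ranges: list[tuple[int, int]] = []
        alleles: set[tuple[int, str]] = set()
        positions: set[int] = set()
        for tok in tokens:
            tok = tok.strip()
            m = _RANGE_RE.match(tok)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if lo > hi:
                    raise ValueError(f"bad range token {tok!r}")
                ranges.append((lo, hi))
                continue
            m = _ALLELE_RE.match(tok)
            if m:
                pos, base = int(m.group(1)), m.group(2).upper()
                if base == "N":
                    positions.add(pos)  # placeholder: always excluded
                else:
                    alleles.add((pos, base))
                continue
            if tok.isdigit():
                positions.add(int(tok))
                continue
            raise ValueError(f"unrecognised exclusion token {tok!r}")
        return cls(
            excluded_ranges=tuple(ranges),
            excluded_alleles=frozenset(alleles),
            excluded_positions=frozenset(positions),
            **kwargs,
        )

    def is_excluded(self, mutation: Mutation) -> bool:
        pos = mutation.position
        if pos in self.excluded_positions:
            return True
        for lo, hi in self.excluded_ranges:
            if lo <= pos <= hi:
                return True
        if mutation.is_substitution or mutation.kind == INSERTION:
            if (pos, mutation.derived_allele) in self.excluded_alleles:
                return True
        return False

    def weight(self, position: int) -> float:
        """Character weight for network building.

        Hotspots get ``reduced_weight``; if a per-position relative rate
        is supplied, the weight falls by 3 per decade of rate above the
        median rate (so a 10x hotspot maps 10 -> 7), floored at 1.
        """
        import math

        w = self.reduced_weight if position in self.downweighted else self.default_weight
        rate = self.per_position_rate.get(position)
        if rate is not None:
            rates = sorted(self.per_position_rate.values())
            median = rates[len(rates) // 2] if rates else 1.0
            if rate > 0 and median > 0:
                w = min(w, self.default_weight - 3.0 * math.log10(rate / median))
        return max(1.0, w)


def apply_position_mask(hap: MitoHaplotype, cfg: PositionConfig) -> MitoHaplotype:
    """Drop all variants at excluded positions; idempotent, input untouched."""
    return hap.with_variants(m for m in hap.variants if not cfg.is_excluded(m))


# ---------------------------------------------------------------------------
# Haplogroup motif calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplogroupDef:
    """A haplogroup label with its defining (and unstable) variants."""

    name: str
    defining_variants: frozenset[Mutation]
    unstable_variants: frozenset[Mutation] = frozenset()

    def __post_init__(self):
        if not self.defining_variants:
            raise ValueError(f"{self.name}: defining_variants must be non-empty")


def polynesian_motif_definitions(reference: str | None = None) -> tuple[HaplogroupDef, ...]:
    """Motif definitions for the B4a1a1 / B4a1a1a pair.

    B4a1a1 is defined by 14022G; B4a1a1a additionally by the classic
    16247G control-region marker, which is flagged unstable because it
    back-mutates repeatedly within the clade.  Under the combined
    analysis mode the two are pooled.
    """
    m14022 = parse_variant_token("14022G", reference)
    m16247 = parse_variant_token("16247G", reference)
    return (
        HaplogroupDef("B4a1a1", frozenset({m14022})),
        HaplogroupDef(
            "B4a1a1a", frozenset({m14022, m16247}), unstable_variants=frozenset({m16247})
        ),
    )


def assign_haplogroup(
    hap: MitoHaplotype,
    defs: Sequence[HaplogroupDef],
    mode: str = "combined",
) -> str:
    """Return the most derived matching label, or ``"unassigned"``.

    A label matches when all its defining variants are present.  In
    ``"combined"`` mode, a label whose *stable* defining variants are all
    present but whose unstable markers are missing does not demote the
    call: the deepest exact match is reported with a ``(PM-combined)``
    tag to show the unstable-marker clade was pooled with it.
    """
    if mode not in ("combined", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    # Order definitions ancestors-first by number of defining variants.
    ordered = sorted(defs, key=lambda d: len(d.defining_variants))
    exact = None
    pooled = False
    for d in ordered:
        if d.defining_variants <= hap.variants:
            exact = d
    if exact is None:
        return "unassigned"
    if mode == "combined":
        for d in ordered:
            if len(d.defining_variants) <= len(exact.defining_variants):
                continue
            stable = d.defining_variants - d.unstable_variants
            missing = d.defining_variants - hap.variants
            if stable <= hap.variants and missing and missing <= d.unstable_variants:
                pooled = True
    return f"{exact.name} (PM-combined)" if pooled else exact.name


# ---------------------------------------------------------------------------
# Dataset reading / writing
# ---------------------------------------------------------------------------

_META_COLUMNS = ("sample_id", "island", "region", "lat", "lon")


def _read_metadata(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise JoinError(f"metadata file missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise JoinError(f"duplicate sample_id in metadata: {dups}")
    return meta.set_index("sample_id")


def diff_against_reference(
    seq: str,
    reference: str | None = None,
    strict: bool = False,
    ambiguous_as_missing: bool = True,
) -> frozenset[Mutation]:
    """Diff an rCRS-aligned sequence (16,569 columns) against the reference.

    Ambiguity codes (N, R, Y, ...) are treated as missing data by
    default; alignment gaps become deletion variants.
    """
    from .reference import reference_sequence

    ref = reference if reference is not None else reference_sequence()
    seq = seq.upper()
    if len(seq) != len(ref):
        if strict:
            raise ValueError(f"sequence length {len(seq)} != {len(ref)}")
        # lenient: compare over the shared prefix
    variants: list[Mutation] = []
    for i, (r, s) in enumerate(zip(ref, seq), start=1):
        if s == r or r == "N":
            continue
        if s == "-":
            variants.append(Mutation(i, "d", DELETION))
            continue
        if s in _AMBIGUOUS:
            if ambiguous_as_missing:
                continue
            raise ValueError(f"ambiguous base {s!r} at position {i}")
        if {s, r} <= _PURINES or {s, r} <= _PYRIMIDINES:
            variants.append(Mutation(i, s, TRANSITION))
        else:
            variants.append(Mutation(i, s, TRANSVERSION))
    return frozenset(variants)


def _read_sequences(seq_path, reference, strict, ambiguous_as_missing):
    seq_path = Path(seq_path)
    with open(seq_path) as fh:
        first = fh.read(1)
    profiles: dict[str, frozenset[Mutation]] = {}
    if first == ">":
        for rec in SeqIO.parse(str(seq_path), "fasta"):
            if strict and len(rec.seq) != MT_LENGTH:
                raise ValueError(
                    f"{rec.id}: FASTA record length {len(rec.seq)} != {MT_LENGTH}"
                )
            profiles[rec.id] = diff_against_reference(
                str(rec.seq), reference, strict=strict,
                ambiguous_as_missing=ambiguous_as_missing,
            )
    else:
        for line in open(seq_path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            sid, tokens = parts[0], parts[1:]
            if tokens == ["."]:
                tokens = []
            if sid in profiles:
                raise JoinError(f"duplicate sample_id in variant table: {sid}")
            profiles[sid] = parse_profile(tokens, reference)
    return profiles


def read_dataset(
    seq_path,
    meta_path,
    reference: str | None = None,
    strict: bool = False,
    ambiguous_as_missing: bool = True,
) -> list[MitoHaplotype]:
    """Read haplotypes (FASTA or variant-profile table) joined to metadata.

    Every sequence record must join exactly one metadata row and vice
    versa; orphans on either side raise :class:`JoinError` naming them.
    """
    profiles = _read_sequences(seq_path, reference, strict, ambiguous_as_missing)
    meta = _read_metadata(meta_path)
    orphan_seqs = sorted(set(profiles) - set(meta.index))
    orphan_meta = sorted(set(meta.index) - set(profiles))
    if orphan_seqs or orphan_meta:
        raise JoinError(
            f"unjoined records — sequences without metadata: {orphan_seqs}; "
            f"metadata without sequences: {orphan_meta}"
        )
    haps = []
    for sid, variants in profiles.items():
        row = meta.loc[sid]
        flags = tuple(str(row["source"]).split(";")) if "source" in meta.columns else ()
        haps.append(
            MitoHaplotype(
                sample_id=sid,
                variants=variants,
                island=str(row["island"]),
                region=str(row["region"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                source_flags=flags,
            )
        )
    return haps


def write_variant_table(haps: Iterable[MitoHaplotype], path) -> None:
    """Write haplotypes as ``sample_id tok tok ...`` lines (``.`` if none)."""
    with open(path, "w") as fh:
        for h in haps:
            toks = " ".join(m.token() for m in sorted(h.variants))
            fh.write(f"{h.sample_id} {toks if toks else '.'}\n")


def write_metadata(haps: Iterable[MitoHaplotype], path) -> None:
    rows = [
        {
            "sample_id": h.sample_id,
            "island": h.island,
            "region": h.region,
            "lat": h.lat,
            "lon": h.lon,
            "source": ";".join(h.source_flags),
        }
        for h in haps
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_position_config(path) -> PositionConfig:
    """Load a YAML position config (excluded tokens, weights, rates)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PositionConfig.from_tokens(
        doc.get("excluded", list(DEFAULT_EXCLUDED_TOKENS)),
        downweighted=frozenset(doc.get("downweighted", DEFAULT_DOWNWEIGHTED)),
        default_weight=float(doc.get("default_weight", 10)),
        reduced_weight=float(doc.get("reduced_weight", 7)),
        per_position_rate={int(k): float(v) for k, v in (doc.get("per_position_rate") or {}).items()},
    )
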