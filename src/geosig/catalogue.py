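"""Mutation classification and catalogue assembly.

Classifies single-base substitutions, doublet substitutions and small
insertions/deletions into the SBS-96 / SBS-288 / DBS-78 / ID-83 channel
schemas and assembles per-sample catalogue matrices (channels x samples,
nonnegative integer counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schemas import (
    BASES,
    ChannelSchema,
    DBS78,
    ID83,
    SBS96,
    SBS288,
    canonical_dbs,
    get_schema,
    reverse_complement,
)

_VALID = set(BASES)


class UnclassifiableError(ValueError):
    """A mutation record that cannot be assigned to any channel."""


@dataclass
class MutationRecord:
    """One somatic variant with its local sequence context.

    Coordinates are 1-based VCF-style; indels are left-aligned with the
    anchor base included in ``ref``/``alt`` (it is stripped before
    classification). ``context5``/``context3`` are the reference sequences
    immediately 5' and 3' of the variant (>=1 nt for SNVs/DBSs, >=10 nt for
    indels). ``strand`` is 'transcribed', 'untranscribed' or 'unknown' and
    is only consulted by the SBS-288 classifier.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context5: str = ""
    context3: str = ""
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not set(self.ref) <= _VALID or not set(self.alt) <= _VALID:
            raise ValueError(f"ref/alt must be over A,C,G,T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_dbs(self) -> bool:
        return (
            len(self.ref) == 2
            and len(self.alt) == 2
            and self.ref[0] != self.alt[0]
            and self.ref[1] != self.alt[1]
        )

    @property
    def is_indel(self) -> bool:
        if len(self.ref) == len(self.alt):
            return False
        shorter, longer = sorted((self.ref, self.alt), key=len)
        return longer.startswith(shorter)


def _check_context(seq: str, n: int, side: str) -> str:
    if len(seq) < n:
        raise UnclassifiableError(f"need >= {n} nt of {side} context, got {len(seq)}")
    return seq


def classify_sbs(mut: MutationRecord) -> str:
    """SBS-96 channel of a single-base substitution.

    Purine-reference mutations are reverse-complemented, flanks included,
    so every SNV lands on one of the 96 pyrimidine-centric channels.
    """
    if not mut.is_snv:
        raise TypeError(f"not an SNV: {mut.ref}>{mut.alt}")
    _check_context(mut.context5, 1, "5'")
    _check_context(mut.context3, 1, "3'")
    five, ref, alt, three = mut.context5[-1], mut.ref, mut.alt, mut.context3[0]
    if not {five, three} <= _VALID:
        raise UnclassifiableError(f"ambiguous context base: {five}..{three}")
    if ref in ("A", "G"):  # canonicalize to pyrimidine reference
        five, three = reverse_complement(three), reverse_complement(five)
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    return f"{five}[{ref}>{alt}]{three}"


_STRAND_CODE = {"transcribed": "T", "untranscribed": "U", "unknown": "N"}


def classify_sbs288(mut: MutationRecord) -> str:
    """SBS-288 channel: SBS-96 label prefixed with the strand component."""
    try:
        code = _STRAND_CODE[mut.strand]
    except KeyError:
        raise ValueError(f"invalid strand annotation: {mut.strand!r}") from None
    return f"{code}:{classify_sbs(mut)}"


def collapse_sbs288_label(label: str) -> str:
    """Project an SBS-288 label onto its SBS-96 component."""
    return label.split(":", 1)[1]


def classify_dbs(mut: MutationRecord) -> str:
    """DBS-78 channel of a doublet substitution (both positions changed)."""
    if len(mut.ref) != 2 or len(mut.alt) != 2:
        raise TypeError(f"not a doublet: {mut.ref}>{mut.alt}")
    if mut.ref[0] == mut.alt[0] or mut.ref[1] == mut.alt[1]:
        raise TypeError(
            "doublet differing at one position is an SNV, not a DBS: "
            f"{mut.ref}>{mut.alt}"
        )
    ref, alt = canonical_dbs(mut.ref, mut.alt)
    return f"{ref}>{alt}"


def _strip_anchor(ref: str, alt: str) -> tuple[str, str]:
    """Remove the shared VCF anchor prefix, returning (deleted, inserted)."""
    i = 0
    while i < len(ref) and i < len(alt) and ref[i] == alt[i]:
        i += 1
    return ref[i:], alt[i:]


def _run_length(seq: str, side5: str, side3: str) -> int:
    """Copies of 1-bp `seq` adjacent to the event site (both directions)."""
    n = 0
    for b in reversed(side5):
        if b != seq:
            break
        n += 1
    for b in side3:
        if b != seq:
            break
        n += 1
    return n


def _tandem_copies(unit: str, side5: str, side3: str) -> int:
    """Full tandem copies of `unit` flanking the event site."""
    n, L = 0, len(unit)
    i = len(side5)
    while i >= L and side5[i - L : i] == unit:
        n += 1
        i -= L
    i = 0
    while i + L <= len(side3) and side3[i : i + L] == unit:
        n += 1
        i += L
    return n


def _microhomology(unit: str, side5: str, side3: str) -> int:
    """Longest partial-unit homology: 3'-prefix or 5'-suffix match of `unit`."""
    best = 0
    for p in range(1, len(unit)):
        if side3[:p] == unit[:p]:
            best = max(best, p)
        if side5[-p:] == unit[-p:]:
            best = max(best, p)
    return best


def classify_indel(mut: MutationRecord) -> str:
    """ID-83 channel of a pure insertion or deletion.

    1-bp events are binned by the pyrimidine-canonicalized base and the
    homopolymer run at the site; longer events by tandem repeat copies of
    the indel'd unit; deletions of >=2 bp with no full extra copy but
    partial-unit homology go to the microhomology channels. Deletion
    repeat categories include the deleted copy (1..6+); insertion
    categories count copies already present (0..5+).
    """
    if not mut.is_indel:
        raise UnclassifiableError(f"complex indel: {mut.ref}>{mut.alt}")
    deleted, inserted = _strip_anchor(mut.ref, mut.alt)
    anchor_len = len(mut.ref) - len(deleted)
    side5 = mut.context5 + mut.ref[:anchor_len]
    side3 = mut.context3
    _check_context(side5, 10, "5'")
    _check_context(side3, 10, "3'")
    if deleted and inserted:
        raise UnclassifiableError(f"complex indel: {mut.ref}>{mut.alt}")
    seq = deleted or inserted
    is_del = bool(deleted)
    L = len(seq)
    if L == 1:
        base = seq if seq in ("C", "T") else reverse_complement(seq)
        run = _run_length(seq, side5, side3)
        if is_del:
            n = min(run + 1, 6)
            return f"1:Del:{base}:{n}"
        return f"1:Ins:{base}:{min(run, 5)}"
    size = min(L, 5)
    copies = _tandem_copies(seq, side5, side3)
    if is_del:
        if copies == 0:
            # homology is < L by construction, so only the 5+ size needs a cap
            mh = min(_microhomology(seq, side5, side3), 5)
            if mh > 0:
                return f"{size}:Del:M:{mh}"
        return f"{size}:Del:R:{min(copies + 1, 6)}"
    return f"{size}:Ins:R:{min(copies, 5)}"


_CLASSIFIERS = {
    "SBS96": classify_sbs,
    "SBS288": classify_sbs288,
    "DBS78": classify_dbs,
    "ID83": classify_indel,
}


def classify(mut: MutationRecord, schema: ChannelSchema | str) -> str:
    name = schema if isinstance(schema, str) else schema.name
    return _CLASSIFIERS[name](mut)


class CatalogueMatrix:
    """Channels x samples nonnegative integer count matrix under a schema."""

    def __init__(
        self,
        schema: ChannelSchema,
        sample_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(schema), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} != "
                f"({len(schema)}, {len(sample_ids)})"
            )
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        self.schema = schema
        self.sample_ids = list(sample_ids)
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def totals(self) -> np.ndarray:
        """Per-sample mutation totals (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.schema.channels), columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schema: ChannelSchema) -> "CatalogueMatrix":
        df = df.reindex(list(schema.channels))
        if df.isna().any().any():
            raise ValueError("frame is missing channels of the schema")
        return cls(schema, list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CatalogueMatrix)
            and self.schema.name == other.schema.name
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


def build_catalogue(
    muts: Iterable[MutationRecord],
    schema: ChannelSchema | str,
    sample_ids: Sequence[str] | None = None,
    skipped_log: list | None = None,
) -> CatalogueMatrix:
    """Classify mutations and tally them into a catalogue matrix.

    Unclassifiable records are skipped and appended to ``skipped_log`` as
    ``(record, reason)`` pairs. Samples listed in ``sample_ids`` get a
    column even with zero classified mutations; unseen samples are appended
    in order of first appearance.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    classifier = _CLASSIFIERS[schema.name]
    samples: list[str] = list(sample_ids) if sample_ids else []
    col = {s: i for i, s in enumerate(samples)}
    tallies: list[dict[int, int]] = [dict() for _ in samples]
    for mut in muts:
        try:
            label = classifier(mut)
        except (UnclassifiableError, TypeError, ValueError) as exc:
            if skipped_log is not None:
                skipped_log.append((mut, str(exc)))
            continue
        if mut.sample_id not in col:
            col[mut.sample_id] = len(samples)
            samples.append(mut.sample_id)
            tallies.append(dict())
        ch = schema.index[label]
        t = tallies[col[mut.sample_id]]
        t[ch] = t.get(ch, 0) + 1
    counts = np.zeros((len(schema), len(samples)), dtype=np.int64)
    for j, t in enumerate(tallies):
        for ch, n in t.items():
            counts[ch, j] = n
    return CatalogueMatrix(schema, samples, counts)


def collapse_sbs288(cat: CatalogueMatrix, drop_unknown: bool = True) -> CatalogueMatrix:
    """Collapse an SBS-288 catalogue to SBS-96 by summing over strand.

    The unknown-strand ('N') bucket is dropped by default so strand-bias
    summaries derived from the T/U split are not silently diluted; pass
    ``drop_unknown=False`` to conserve totals instead.
    """
    if cat.schema.name != "SBS288":
        raise ValueError("expected an SBS-288 catalogue")
    counts = np.zeros((96, cat.n_samples), dtype=np.int64)
    for i, label in enumerate(cat.schema.channels):
        strand, label96 = label.split(":", 1)
        if drop_unknown and strand == "N":
            continue
        counts[SBS96.index[label96]] += cat.counts[i]
    return CatalogueMatrix(SBS96, cat.sample_ids, counts)


def six_class_profile(cat: CatalogueMatrix) -> pd.DataFrame:
    """Proportions of the six primary substitution classes per sample.

    Returns a 6 x samples DataFrame; zero-mutation samples get NaN columns
    (flagged undefined, to be excluded from downstream ordination).
    """
    if cat.schema.name != "SBS96":
        raise ValueError("six-class profile requires an SBS-96 catalogue")
    classes = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    rows = np.array([[lab[2:5] == c for lab in cat.schema.channels] for c in classes])
    sums = rows @ cat.counts  # 6 x samples
    totals = cat.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = sums / np.where(totals > 0, totals, np.nan)
    return pd.DataFrame(props, index=classes, columns=cat.sample_ids)
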