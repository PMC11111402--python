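"""Channel schemas for mutation classification.

A channel schema is a fixed, ordered partition of somatic mutations into
classes: SBS-96 (single-base substitution in pyrimidine-centric trinucleotide
context), SBS-288 (SBS-96 crossed with transcriptional strand), DBS-78
(canonical doublet-base substitutions) and ID-83 (small insertions/deletions
by type, length, repeat context and microhomology).
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the six pyrimidine-centric substitution classes, in conventional order
SBS_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical DBS-78 reference doublets, in conventional order
DBS_REF_DOUBLETS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")

#: strand components of SBS-288: transcribed, untranscribed, unknown
STRAND_CODES = ("T", "U", "N")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered list of channel labels under a named classification."""

    name: str
    channels: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(
            self, "index", {c: i for i, c in enumerate(self.channels)}
        )

    def __len__(self) -> int:
        return len(self.channels)


def _sbs96_labels() -> list[str]:
    # substitution-major order: all 16 contexts of C>A, then C>G, ... T>G;
    # contexts ordered 5' base then 3' base, each A,C,G,T
    labels = []
    for sub in SBS_CLASSES:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    assert len(labels) == 96
    return labels


def _sbs288_labels() -> list[str]:
    # strand-major: T (transcribed), U (untranscribed), N (unknown)
    return [f"{s}:{lab}" for s in STRAND_CODES for lab in _sbs96_labels()]


def canonical_dbs(ref: str, alt: str) -> tuple[str, str]:
    """Map a doublet substitution to its canonical (ref, alt) orientation.

    Non-canonical reference doublets are reverse-complemented; for the four
    palindromic references (AT, CG, GC, TA) the alt-orientation tie is broken
    toward the lexicographically smaller of alt and its reverse complement.
    """
    if ref not in DBS_REF_DOUBLETS:
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    if ref == reverse_complement(ref):  # palindromic reference
        alt = min(alt, reverse_complement(alt))
    return ref, alt


def _dbs78_labels() -> list[str]:
    labels = []
    for ref in DBS_REF_DOUBLETS:
        alts = set()
        for a0 in BASES:
            for a1 in BASES:
                if a0 == ref[0] or a1 == ref[1]:
                    continue
                _, alt = canonical_dbs(ref, a0 + a1)
                alts.add(alt)
        labels.extend(f"{ref}>{alt}" for alt in sorted(alts))
    assert len(labels) == 78
    return labels


def _id83_labels() -> list[str]:
    # 1-bp deletions: categories = copies of the deleted base in the
    # reference homopolymer including the deleted one (1..6, 6 = 6+)
    labels = [f"1:Del:{b}:{n}" for b in ("C", "T") for n in range(1, 7)]
    # 1-bp insertions: copies already present (0..5, 5 = 5+)
    labels += [f"1:Ins:{b}:{n}" for b in ("C", "T") for n in range(0, 6)]
    # >=2 bp deletions at repeats: unit copies including the deleted one
    labels += [f"{l}:Del:R:{n}" for l in (2, 3, 4, 5) for n in range(1, 7)]
    # >=2 bp insertions at repeats: unit copies already present
    labels += [f"{l}:Ins:R:{n}" for l in (2, 3, 4, 5) for n in range(0, 6)]
    # microhomology deletions: homology 1..len-1, except 5+ bp where 1..5
    labels += [
        f"{l}:Del:M:{m}" for l in (2, 3, 4, 5) for m in range(1, 6 if l == 5 else l)
    ]
    assert len(labels) == 83
    return labels


SBS96 = ChannelSchema("SBS96", tuple(_sbs96_labels()))
SBS288 = ChannelSchema("SBS288", tuple(_sbs288_labels()))
DBS78 = ChannelSchema("DBS78", tuple(_dbs78_labels()))
ID83 = ChannelSchema("ID83", tuple(_id83_labels()))

SCHEMAS = {s.name: s for s in (SBS96, SBS288, DBS78, ID83)}


def get_schema(name: str) -> ChannelSchema:
    try:
        return SCHEMAS[name]
    except KeyError:
        raise KeyError(
            f"unknown schema {name!r}; available: {sorted(SCHEMAS)}"
        ) from None
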