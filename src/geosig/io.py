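"""Readers and writers for the pipeline's tabular formats.

Catalogue matrices travel as SigProfiler-compatible TSV (a ``MutationType``
column of channel labels plus one column per sample); signature profiles as
COSMIC-dialect CSV (a ``Type`` column plus one column per signature).
Mutation records are read from minimal VCF 4.x (CHROM/POS/REF/ALT, optional
gzip) or from a tabular TSV that carries the local sequence context.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .catalogue import CatalogueMatrix, MutationRecord
from .schemas import ChannelSchema, get_schema


def write_catalogue_tsv(cat: CatalogueMatrix, path: str | Path) -> None:
    df = cat.to_frame()
    df.insert(0, "MutationType", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_catalogue_tsv(path: str | Path, schema: ChannelSchema | str) -> CatalogueMatrix:
    if isinstance(schema, str):
        schema = get_schema(schema)
    df = pd.read_csv(path, sep="\t", dtype={"MutationType": str})
    df = df.set_index("MutationType")
    return CatalogueMatrix.from_frame(df, schema)


def write_signatures_csv(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write column-stochastic profiles (channels x signatures) as COSMIC CSV."""
    out = profiles.copy()
    out.insert(0, "Type", out.index)
    out.to_csv(path, index=False)


def read_signatures_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.set_index("Type")
    df.index.name = "Type"
    return df


def write_exposures_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_exposures_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# mutation records

_MUT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "context5",
    "context3",
    "strand",
]


def write_mutations_tsv(muts: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [[getattr(m, c) for c in _MUT_COLUMNS] for m in muts]
    pd.DataFrame(rows, columns=_MUT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        MutationRecord(
            sample_id=r.sample_id,
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            context5=r.context5,
            context3=r.context3,
            strand=r.strand or "unknown",
        )
        for r in df.itertuples()
    ]


class FastaContextProvider:
    """Looks up flanking sequence from a FASTA reference for real VCFs.

    A plain in-memory reader is sufficient here because synthetic data carry
    their own context; genome-scale use should memory-map via pyfaidx, which
    exposes the same ``fetch`` semantics.
    """

    def __init__(self, path: str | Path) -> None:
        self.sequences: dict[str, str] = {}
        name, chunks = None, []
        with _open_text(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        self.sequences[name] = "".join(chunks)
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line.upper())
        if name is not None:
            self.sequences[name] = "".join(chunks)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice of the reference."""
        seq = self.sequences[chrom]
        return seq[max(start - 1, 0) : end]

    def context(self, chrom: str, pos: int, ref_len: int, flank: int) -> tuple[str, str]:
        c5 = self.fetch(chrom, pos - flank, pos - 1)
        c3 = self.fetch(chrom, pos + ref_len, pos + ref_len - 1 + flank)
        return c5, c3


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_vcf(
    path: str | Path,
    sample_id: str | None = None,
    context_provider: FastaContextProvider | None = None,
    flank: int = 12,
) -> Iterator[MutationRecord]:
    """Parse a minimal VCF 4.x into mutation records.

    Per-sample context comes either from a FASTA-backed provider or from
    ``CTX5``/``CTX3`` INFO keys (the simulator writes the latter so no
    genome is needed). The sample id defaults to the first genotype-column
    name, falling back to the file stem.
    """
    path = Path(path)
    default_sample = sample_id
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if default_sample is None:
                    default_sample = cols[9] if len(cols) > 9 else path.stem.replace(".vcf", "")
                continue
            fields = line.split("\t")
            chrom, pos, _id, ref, alt = fields[:5]
            info = fields[7] if len(fields) > 7 else ""
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            sample = kv.get("SAMPLE", default_sample or path.stem)
            c5, c3 = kv.get("CTX5", ""), kv.get("CTX3", "")
            if context_provider is not None:
                c5, c3 = context_provider.context(chrom, int(pos), len(ref), flank)
            for alt_allele in alt.split(","):
                yield MutationRecord(
                    sample_id=sample,
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt_allele,
                    context5=c5,
                    context3=c3,
                )


def write_vcf(muts: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as minimal VCF with context carried in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
        fh.write('##INFO=<ID=CTX5,Number=1,Type=String,Description="5-prime context">\n')
        fh.write('##INFO=<ID=CTX3,Number=1,Type=String,Description="3-prime context">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in muts:
            info = f"SAMPLE={m.sample_id};CTX5={m.context5};CTX3={m.context3}"
            fh.write(f"{m.chrom}\t{m.pos}\t.\t{m.ref}\t{m.alt}\t.\t.\t{info}\n")
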