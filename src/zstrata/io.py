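"""Readers and writers for the on-disk formats the pipeline consumes.

FASTA via Biopython; BED-like and generic TSV tables via pandas with schema
checks. All genomic intervals are 0-based half-open internally and on disk
(BED native); 1-based inclusive input dialects must be converted at the
boundary with ``one_based=True``. Missing values in TSVs are written as '.'.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_tsv_table",
    "write_tsv",
    "read_snp_table",
]

MISSING = "."


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Sequences are preserved verbatim (case included). Duplicate ids raise;
    an empty file returns an empty mapping with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        warnings.warn(f"{path}: empty FASTA")
    return out


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_tsv_table(
    path: str | Path, schema: dict[str, type], keep_extra: bool = True
) -> pd.DataFrame:
    """Read a TSV with a typed schema.

    ``schema`` maps required column names to types; missing columns raise,
    extra columns are preserved untyped (``keep_extra=False`` drops them).
    '.' is the missing-value token.
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col, typ in schema.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: column {col!r} not coercible to {typ}") from exc
    if not keep_extra:
        df = df[list(schema)]
    return df


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_bed(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED-like table (chrom, start, end, [name, score, ...]).

    Headerless 3+ column BED; intervals validated as half-open with
    end > start (after optional 1-based conversion). Violations report the
    offending line number.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns")
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] >= 4:
        names[3] = "name"
    if df.shape[1] >= 5:
        names[4] = "score"
    df.columns = names
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if one_based:
        df["start"] -= 1
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(
            f"{path}: end <= start at line {int(bad[0]) + 1} "
            f"({df.loc[bad[0], 'chrom']}:{df.loc[bad[0], 'start']}-{df.loc[bad[0], 'end']})"
        )
    return df


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a SNP table: TSV (chrom, pos, depth, ref, alt) or minimal VCF.

    VCF input (detected by ``##fileformat`` or a ``#CHROM`` header) reads
    CHROM, POS (converted to 0-based), REF, ALT and the INFO ``DP`` field.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat") or first.startswith("#CHROM"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, pos, _, ref, alt = fields[0], int(fields[1]), *fields[2:5]
                dp = None
                for kv in fields[7].split(";"):
                    if kv.startswith("DP="):
                        dp = int(kv[3:])
                if dp is None:
                    raise ValueError(f"{path}: VCF record without INFO DP at {chrom}:{pos}")
                rows.append(
                    {"chrom": chrom, "pos": pos - 1, "depth": dp, "ref": ref, "alt": alt}
                )
        return pd.DataFrame(rows)
    return read_tsv_table(
        path, {"chrom": str, "pos": int, "depth": int, "ref": str, "alt": str}
    )
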