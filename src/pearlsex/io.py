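"""File readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (first column contig id, header row of sample ids);
metadata and Ct tables as CSV (``sample_id,histo_sex,histo_stage,
molecular_label`` and ``sample_id,gene_id,replicate,ct`` respectively).
Dialects are fixed — UTF-8, '.' decimal, no thousands separators — so
write-then-read round trips are exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_GENE_ORDER,
    REFERENCE_GENES,
    CountMatrix,
    CtTable,
    MolecularLabel,
    RelExprTable,
    validate_category,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_ct",
    "write_ct",
    "read_relexpr",
    "write_relexpr",
    "provenance_header",
]


def read_counts(path: str | Path) -> CountMatrix:
    """Read a contigs x samples TSV count matrix.

    Ragged rows, duplicate contig ids, negative or non-integer counts are
    errors citing the offending line.
    """
    path = Path(path)
    with path.open() as fh:
        header: list[str] | None = None
        contig_ids: list[str] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                if not header:
                    raise ValueError(f"{path}:{lineno}: header has no sample columns")
                continue
            if len(parts) != len(header) + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts) - 1} values, "
                    f"expected {len(header)})"
                )
            cid = parts[0]
            if cid in seen:
                raise ValueError(f"{path}:{lineno}: duplicated contig id {cid!r}")
            seen.add(cid)
            vals = []
            for v in parts[1:]:
                try:
                    f = float(v)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric count {v!r}") from None
                if f < 0:
                    raise ValueError(f"{path}:{lineno}: negative count {v}")
                if f != int(f):
                    raise ValueError(f"{path}:{lineno}: non-integer count {v}")
                vals.append(int(f))
            contig_ids.append(cid)
            rows.append(vals)
    if header is None:
        raise ValueError(f"{path}: empty counts file")
    return CountMatrix(
        contig_ids=contig_ids,
        sample_ids=list(header),
        counts=np.array(rows, dtype=np.int64),
    )


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("contig_id\t" + "\t".join(cm.sample_ids) + "\n")
        for cid, row in zip(cm.contig_ids, cm.counts):
            fh.write(cid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata CSV; molecular labels validated when present."""
    meta = pd.read_csv(path, dtype=str)
    required = {"sample_id", "histo_sex", "histo_stage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    if "molecular_label" in meta.columns:
        for _, row in meta.iterrows():
            validate_category(row["histo_sex"], row["histo_stage"], row["molecular_label"])
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_ct(
    path: str | Path,
    reference_genes: tuple[str, ...] = REFERENCE_GENES,
) -> CtTable:
    """Read a long-format Ct CSV (sample_id, gene_id, replicate, ct)."""
    rec = pd.read_csv(path)
    required = {"sample_id", "gene_id", "replicate", "ct"}
    missing = required - set(rec.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    genes = set(rec["gene_id"])
    roles = {g: ("reference" if g in reference_genes else "target") for g in genes}
    return CtTable(records=rec, gene_roles=roles)


def write_ct(table: CtTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


def read_relexpr(path: str | Path) -> RelExprTable:
    df = pd.read_csv(path, index_col=0)
    return RelExprTable(values=df)


def write_relexpr(rel: RelExprTable, path: str | Path) -> None:
    rel.values.to_csv(path)


def provenance_header(seed: int | None, params: dict) -> str:
    """Comment block recording seed, package version and a config hash."""
    from . import __version__

    blob = json.dumps(params, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    lines = [
        f"# pearlsex v{__version__}",
        f"# seed: {seed}",
        f"# config_sha256: {digest}",
    ]
    return "\n".join(lines) + "\n"
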