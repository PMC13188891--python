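"""Readers and writers: allele-depth TSV, amplicon TSV, BED, JSON reports.

Internal coordinates are 1-based inclusive; BED export converts to 0-based
half-open (start-1, end) and the reader converts back.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exceptions import FormatError
from .finemap import REQUIRED_COLUMNS as AMPLICON_COLUMNS
from .finemap import MappedInterval

DEPTH_COLUMNS = ["chrom", "pos", "depth_R", "depth_S"]


def _read_strict_tsv(path, required, int_cols):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    bad_lines = []
    for col in int_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced < 0) | (coerced % 1 != 0)
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = coerced
    if bad_lines:
        raise FormatError(f"{path}: malformed rows", lines=sorted(set(bad_lines)))
    for col in int_cols:
        df[col] = df[col].astype("int64")
    return df[required]


def read_allele_depth_table(path, orientation: dict | None = None) -> pd.DataFrame:
    """Read a pooled allele-depth table (TSV, or VCF with an AD field).

    TSV needs columns ``chrom, pos, depth_R, depth_S`` with depth_R counting
    the resistant-strain-derived allele. For VCF input, ``orientation`` maps
    (chrom, pos) to "REF" or "ALT", naming which allele is resistant-derived;
    sites absent from the map are skipped.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        return _read_vcf_allele_depths(path, orientation)
    return _read_strict_tsv(path, DEPTH_COLUMNS, ["pos", "depth_R", "depth_S"])


def _read_vcf_allele_depths(path, orientation):
    from cyvcf2 import VCF

    if orientation is None:
        raise FormatError("VCF input needs an orientation table ((chrom,pos) -> REF/ALT)")
    rows = []
    for v in VCF(str(path)):
        key = (v.CHROM, v.POS)
        side = orientation.get(key)
        if side is None:
            continue
        ad = v.format("AD")
        if ad is None:
            raise FormatError(f"{path}: record {v.CHROM}:{v.POS} lacks an AD field")
        ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
        depth_r = ref_d if side == "REF" else alt_d
        rows.append((v.CHROM, v.POS, depth_r, ref_d + alt_d - depth_r))
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)


def write_allele_depth_table(records: pd.DataFrame, path) -> None:
    records[DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_amplicon_table(path) -> pd.DataFrame:
    """Read a paired-pool amplicon count table (TSV)."""
    int_cols = [c for c in AMPLICON_COLUMNS if c not in ("chrom",)]
    return _read_strict_tsv(path, AMPLICON_COLUMNS, int_cols)


def write_amplicon_table(records: pd.DataFrame, path) -> None:
    records[AMPLICON_COLUMNS].to_csv(path, sep="\t", index=False)


def write_interval_bed(interval: MappedInterval | None, path) -> None:
    """Write the mapped interval as BED (0-based half-open).

    ``None`` produces a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("# candidate interval (BED: 0-based half-open)\n")
        if interval is not None:
            fh.write(
                f"{interval.chrom}\t{interval.start - 1}\t{interval.end}\t"
                f"{interval.width_kb_display.replace(' ', '')}\n"
            )


def read_interval_bed(path) -> MappedInterval | None:
    """Read a BED interval back into 1-based inclusive coordinates."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: malformed BED line: {line!r}")
            return MappedInterval(chrom=parts[0], start=int(parts[1]) + 1, end=int(parts[2]))
    return None


def write_json_report(report: dict, path) -> None:
    """Canonical JSON (sorted keys, fixed separators): byte-stable per seed."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
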