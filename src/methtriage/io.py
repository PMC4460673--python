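"""Readers and writers for every on-disk format the pipeline touches.

All genomic intervals are handled internally as **0-based half-open**
``[start, end)``; cytosine reports are the only 1-based input and are
converted here, at the boundary, so no other module performs coordinate
arithmetic.

Dialects
--------
cytosine report
    Headerless TSV, one row per cytosine as emitted by bisulfite aligners:
    ``chrom  pos(1-based)  strand(+/-)  meth_count  unmeth_count``.
    Extra trailing columns (e.g. context fields) are ignored.
amplicons / peaks
    BED3+ (0-based half-open).  Amplicon names encode ``gene|amplicon_name``
    in the BED name column.
manifest, Ct table, CNV calls, miRNA matrix, target map
    Header-carrying TSV; columns are matched by name, so column order may
    vary freely.  Missing numeric values are written/read as ``NA``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, ValidationError

TISSUES = ("tumor", "non_tumor", "precursor", "normal")
CNV_STATES = ("gain", "none", "loss")

#: canonical chromatin feature tracks the annotation step knows about
CHROMATIN_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "DNase")

CPG_COLUMNS = ["sample_id", "chrom", "pos", "meth_count", "unmeth_count"]


@dataclass(frozen=True)
class CpGCounts:
    """Methylated/unmethylated read counts at one CpG in one sample.

    ``pos`` is the 1-based coordinate of the forward-strand cytosine of the
    CpG dinucleotide (reverse-strand calls are collapsed onto it).
    """

    sample_id: str
    chrom: str
    pos: int
    meth_count: int
    unmeth_count: int

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count


@dataclass(frozen=True)
class AmpliconDef:
    """A targeted PCR amplicon: the unit over which CpG methylation is averaged."""

    gene: str
    amplicon_name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    n_cpg_expected: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"amplicon {self.amplicon_name}: start ({self.start}) must be "
                f"< end ({self.end})"
            )

    def contains(self, pos_1based: int) -> bool:
        """Whether a 1-based position falls inside the half-open interval."""
        return self.start < pos_1based <= self.end


def read_cytosine_report(path, min_depth: int = 10, sample_id: str | None = None) -> pd.DataFrame:
    """Read a per-CpG cytosine report and collapse strands.

    Reverse-strand records (the G of the CpG, at forward position + 1) are
    summed onto the forward-strand cytosine.  Records whose post-collapse
    total depth is below ``min_depth`` are dropped.

    Parameters
    ----------
    path
        Headerless TSV: chrom, 1-based position, strand (+/-), methylated
        count, unmethylated count.  Extra columns are ignored.
    min_depth
        Minimum combined read depth per CpG after strand collapsing (>= 1).
    sample_id
        Sample label attached to every record; defaults to the file stem.

    Returns
    -------
    DataFrame with columns ``sample_id, chrom, pos, meth_count, unmeth_count``
    sorted by (chrom, pos).
    """
    path = Path(path)
    if min_depth < 1:
        raise ValidationError(f"min_depth must be >= 1, got {min_depth}")
    if sample_id is None:
        sample_id = path.stem

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated test fixtures
                fields = line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"expected >= 5 columns (chrom, pos, strand, meth, unmeth), "
                    f"got {len(fields)}", path=path, line=lineno,
                )
            chrom, pos_s, strand, meth_s, unmeth_s = fields[:5]
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"non-integer field: {exc}", path=path, line=lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"strand must be + or -, got {strand!r}", path=path, line=lineno)
            if pos < 1:
                raise ParseError(f"position must be >= 1, got {pos}", path=path, line=lineno)
            if meth < 0 or unmeth < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative read count ({meth}/{unmeth})"
                )
            # collapse the reverse-strand G onto the forward-strand C
            if strand == "-":
                pos -= 1
                if pos < 1:
                    raise ParseError(
                        "reverse-strand record at position 1 cannot be collapsed",
                        path=path, line=lineno,
                    )
            rows.append((chrom, pos, meth, unmeth))

    if not rows:
        return pd.DataFrame(columns=CPG_COLUMNS).astype(
            {"pos": int, "meth_count": int, "unmeth_count": int}
        )

    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_count", "unmeth_count"])
    df = df.groupby(["chrom", "pos"], as_index=False, sort=True).sum()
    df = df[df.meth_count + df.unmeth_count >= min_depth].reset_index(drop=True)
    df.insert(0, "sample_id", sample_id)
    return df


def _read_bed_rows(path) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 columns", path=path, line=lineno)
            yield lineno, fields


def read_amplicon_bed(path) -> list[AmpliconDef]:
    """Read amplicon definitions from BED3+ whose name column is ``gene|amplicon``.

    A name column without ``|`` is used as both gene and amplicon name.
    Duplicate amplicon names are rejected.
    """
    path = Path(path)
    out: list[AmpliconDef] = []
    seen: set[str] = set()
    for lineno, fields in _read_bed_rows(path):
        chrom, start_s, end_s = fields[:3]
        if len(fields) < 4 or not fields[3]:
            raise ParseError("amplicon BED requires a name column (gene|amplicon)",
                             path=path, line=lineno)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate: {exc}", path=path, line=lineno)
        name = fields[3]
        gene, _, amplicon_name = name.partition("|")
        if not amplicon_name:
            amplicon_name = gene
        if amplicon_name in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate amplicon name {amplicon_name!r}")
        seen.add(amplicon_name)
        try:
            out.append(AmpliconDef(gene=gene, amplicon_name=amplicon_name,
                                   chrom=chrom, start=start, end=end))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}")
    return out


def read_sample_manifest(path) -> pd.DataFrame:
    """Read the sample manifest and validate tumor/non-tumor pairing.

    The manifest is a header TSV with columns ``sample_id, patient_id,
    tissue`` (tissue in {tumor, non_tumor, precursor, normal}).  A patient
    may contribute at most one tumor and one non_tumor sample; violations
    raise.  Unpaired tumor-cohort samples are retained with a warning.
    """
    df = _read_header_tsv(path, required={"sample_id", "patient_id", "tissue"})
    df = df[["sample_id", "patient_id", "tissue"]].astype(str)
    bad = sorted(set(df.tissue) - set(TISSUES))
    if bad:
        raise ValidationError(f"{path}: unknown tissue label(s) {bad}; expected one of {TISSUES}")
    if df.sample_id.duplicated().any():
        dups = df.sample_id[df.sample_id.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate sample_id(s) {dups}")
    for (patient, tissue), grp in df[df.tissue.isin(["tumor", "non_tumor"])].groupby(
            ["patient_id", "tissue"]):
        if len(grp) > 1:
            raise ValidationError(
                f"{path}: patient {patient!r} has {len(grp)} {tissue} samples; expected 1"
            )
    unpaired = [p for p, g in df[df.tissue.isin(["tumor", "non_tumor"])].groupby("patient_id")
                if set(g.tissue) != {"tumor", "non_tumor"}]
    if unpaired:
        warnings.warn(f"unpaired patients retained (no paired test possible): {unpaired}")
    return df.reset_index(drop=True)


def paired_patients(manifest: pd.DataFrame) -> pd.DataFrame:
    """Return one row per complete tumor/non-tumor pair.

    Columns: ``patient_id, tumor_sample, nontumor_sample``, sorted by patient.
    """
    sub = manifest[manifest.tissue.isin(["tumor", "non_tumor"])]
    wide = sub.pivot(index="patient_id", columns="tissue", values="sample_id")
    wide = wide.dropna(subset=["tumor", "non_tumor"]) if {"tumor", "non_tumor"} <= set(
        wide.columns) else wide.iloc[0:0].reindex(columns=["tumor", "non_tumor"])
    out = wide.reset_index().rename(
        columns={"tumor": "tumor_sample", "non_tumor": "nontumor_sample"})
    return out[["patient_id", "tumor_sample", "nontumor_sample"]].sort_values(
        "patient_id").reset_index(drop=True)


_TABULAR_KINDS = {
    "ct_table": {"sample_id", "gene", "ct_target", "ct_reference"},
    "expression_matrix": None,   # gene + one column per array
    "cnv_calls": {"sample_id", "gene", "state"},
    "mirna_matrix": None,        # mirna + one column per sample
    "target_map": {"mirna", "gene"},
}


def _read_header_tsv(path, required: set[str] | None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                         keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        if required is not None:  # an empty file is an empty collection
            return pd.DataFrame(columns=sorted(required))
        raise ParseError("empty file (missing header)", path=path)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(str(exc), path=path)
    if required is not None:
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"missing required column(s) {sorted(missing)}", path=path)
    return df


def read_tabular_inputs(path, kind: str) -> pd.DataFrame:
    """Read one of the fixed-header TSV inputs.

    ``kind`` selects the dialect:

    * ``ct_table``: sample_id, gene, ct_target, ct_reference (Ct values may
      be NA; NA rows are retained with a missing flag, to be excluded from
      that gene's statistics downstream).
    * ``expression_matrix``: ``gene`` column + one numeric column per array.
    * ``cnv_calls``: sample_id, gene, state in {gain, none, loss}.
    * ``mirna_matrix``: ``mirna`` column + one log2 column per sample (NA =
      undetected).
    * ``target_map``: mirna, gene pairs.
    """
    if kind not in _TABULAR_KINDS:
        raise ValidationError(f"unknown tabular kind {kind!r}; expected one of "
                              f"{sorted(_TABULAR_KINDS)}")
    df = _read_header_tsv(path, _TABULAR_KINDS[kind])

    if kind == "ct_table":
        for col in ("ct_target", "ct_reference"):
            try:
                df[col] = pd.to_numeric(df[col])
            except ValueError as exc:
                raise ValidationError(f"{path}: non-numeric {col}: {exc}")
        df["missing"] = df.ct_target.isna() | df.ct_reference.isna()
        return df[["sample_id", "gene", "ct_target", "ct_reference", "missing"]]

    if kind == "cnv_calls":
        bad = sorted(set(df.state.dropna()) - set(CNV_STATES))
        if bad:
            raise ValidationError(f"{path}: unknown CNV state(s) {bad}; "
                                  f"expected one of {CNV_STATES}")
        if df.duplicated(["sample_id", "gene"]).any():
            raise ValidationError(f"{path}: duplicate (sample_id, gene) CNV calls")
        return df[["sample_id", "gene", "state"]]

    if kind == "target_map":
        return df[["mirna", "gene"]].drop_duplicates().reset_index(drop=True)

    # matrices: first id column, remaining columns numeric
    id_col = "gene" if kind == "expression_matrix" else "mirna"
    if id_col not in df.columns:
        raise ParseError(f"missing required column(s) ['{id_col}']", path=path)
    value_cols = [c for c in df.columns if c != id_col]
    out = df.set_index(id_col)[value_cols]
    try:
        out = out.apply(pd.to_numeric)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric matrix entry: {exc}")
    out.index.name = id_col
    return out


class PeakSet:
    """A set of peaks (0-based half-open intervals) for one mark in one cell line."""

    def __init__(self, mark: str, cell_line: str,
                 intervals: Iterable[tuple[str, int, int]] = ()):
        self.mark = mark
        self.cell_line = cell_line
        self._trees: dict[str, IntervalTree] = {}
        self.n_peaks = 0
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValidationError(f"peak on {chrom}: start ({start}) must be < end ({end})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        self.n_peaks += 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False

    def count_overlaps(self, chrom: str, start: int, end: int) -> int:
        tree = self._trees.get(chrom)
        return len(tree.overlap(start, end)) if tree is not None else 0

    def __len__(self) -> int:
        return self.n_peaks

    def __repr__(self) -> str:
        return f"PeakSet(mark={self.mark!r}, cell_line={self.cell_line!r}, n={self.n_peaks})"


def read_peak_bed(path, mark: str, cell_line: str) -> PeakSet:
    """Read a BED3+ peak track into an overlap-queryable :class:`PeakSet`."""
    peaks = PeakSet(mark=mark, cell_line=cell_line)
    for lineno, fields in _read_bed_rows(path):
        chrom, start_s, end_s = fields[:3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate: {exc}", path=path, line=lineno)
        try:
            peaks.add(chrom, start, end)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}")
    return peaks


def write_report(results, path, format: str = "tsv") -> None:
    """Write a stage report as TSV (printed precision) or JSON (full precision).

    ``results`` is a DataFrame or a list of dataclass/dict records.  Column
    order is the DataFrame's column order and is fixed by each producing
    stage.  TSV uses ``NA`` for missing values and a fixed ``%.6g`` float
    format so identical inputs yield byte-identical files.
    """
    df = _as_frame(results)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    elif format == "json":
        payload = {"columns": list(df.columns),
                   "records": json.loads(df.to_json(orient="records"))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown report format {format!r}; expected tsv or json")


def read_report(path, format: str = "tsv") -> pd.DataFrame:
    """Read back a file produced by :func:`write_report`."""
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["records"], columns=payload["columns"])
    raise ValidationError(f"unknown report format {format!r}; expected tsv or json")


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    records = []
    for item in results:
        if hasattr(item, "__dataclass_fields__"):
            from dataclasses import asdict
            records.append(asdict(item))
        elif isinstance(item, dict):
            records.append(item)
        else:
            raise ValidationError(f"cannot serialise record of type {type(item).__name__}")
    return pd.DataFrame(records)
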