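"""File I/O: model-spec tables, cohort matrices, and provenance-stamped TSV.

Canonical dialect is UTF-8 TSV with '#' comment lines (CSV accepted on
read; CRLF tolerated). Numeric outputs are written at full precision
(shortest round-trip repr). Cohort files carry a provenance block as leading
'# key: json' comment lines.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError, ValidationError
from .model_spec import DiseaseModel, LocusEffect, make_locus
from .nb_classifier import MISSING, Cohort

__all__ = [
    "read_model_spec",
    "write_model_spec",
    "read_cohort",
    "write_cohort",
    "write_table",
]


def _read_text(path) -> str:
    try:
        return Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc


def _split_comments(text: str) -> tuple[list[str], list[str]]:
    comments, rows = [], []
    for line in text.splitlines():
        if line.lstrip().startswith("#"):
            comments.append(line.lstrip()[1:].strip())
        elif line.strip():
            rows.append(line)
    return comments, rows


def _sniff_sep(header: str) -> str:
    return "\t" if "\t" in header else ","


def _numeric_column(df: pd.DataFrame, col: str, path, required: bool = True):
    """Convert a column to float, naming the offending row/column on failure."""
    if col not in df.columns:
        if required:
            raise InputError(f"{path}: missing required column {col!r}")
        return None
    raw = df[col]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise InputError(
            f"{path}: non-numeric value {raw.iloc[i]!r} in column {col!r}, "
            f"data row {i + 1}"
        )
    return converted


def read_model_spec(
    path,
    prior: float,
    population_mode: str = "marginal_independent",
    mapping: str = "freq_ratio",
    percent: bool = False,
) -> DiseaseModel:
    """Read a one-locus-per-row model table (columns locus_id, g0, rr[, weight])."""
    comments, rows = _split_comments(_read_text(path))
    if not rows:
        raise InputError(f"{path}: no data rows")
    sep = _sniff_sep(rows[0])
    df = pd.read_csv(_io.StringIO("\n".join(rows)), sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "locus_id" not in df.columns:
        raise InputError(f"{path}: missing required column 'locus_id'")
    ids = df["locus_id"].astype(str).str.strip()
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise InputError(f"{path}: duplicate locus_id {dup!r}")
    g0 = _numeric_column(df, "g0", path)
    rr = _numeric_column(df, "rr", path)
    weight = _numeric_column(df, "weight", path, required=False)
    scale = 0.01 if percent else 1.0
    loci = []
    for i in range(len(df)):
        w = None
        if weight is not None and not pd.isna(weight.iloc[i]):
            w = float(weight.iloc[i])
        try:
            loci.append(
                make_locus(
                    g0=float(g0.iloc[i]) * scale,
                    rr=float(rr.iloc[i]),
                    mapping=mapping,
                    prior=prior,
                    locus_id=ids.iloc[i],
                    weight=w,
                )
            )
        except ValidationError as exc:
            raise InputError(f"{path}: data row {i + 1}: {exc}") from exc
    return DiseaseModel(prior=prior, loci=tuple(loci), population_mode=population_mode)


def write_model_spec(model: DiseaseModel, path, provenance: dict | None = None) -> None:
    lines = _provenance_lines(
        {"prior": model.prior, "population_mode": model.population_mode}
        | (provenance or {})
    )
    lines.append("locus_id\tg0\trr\tweight")
    for l in model.loci:
        w = "" if l.weight is None else repr(l.weight)
        lines.append(f"{l.locus_id}\t{l.g0!r}\t{l.rr!r}\t{w}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _provenance_lines(provenance: dict) -> list[str]:
    merged = {"tool": f"genoprog {__version__}"} | provenance
    return [f"# {k}: {json.dumps(v)}" for k, v in merged.items()]


def _parse_provenance(comments: list[str]) -> dict:
    out = {}
    for c in comments:
        if ":" in c:
            k, v = c.split(":", 1)
            try:
                out[k.strip()] = json.loads(v.strip())
            except json.JSONDecodeError:
                out[k.strip()] = v.strip()
    return out


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as TSV: subject_id, label, one column per locus; NA missing."""
    lines = _provenance_lines(cohort.provenance)
    lines.append("subject_id\tlabel\t" + "\t".join(cohort.locus_ids))
    for i in range(cohort.n_subjects):
        states = [
            "NA" if s == MISSING else str(int(s)) for s in cohort.genotypes[i]
        ]
        lines.append(f"{cohort.ids[i]}\t{cohort.labels[i]}\t" + "\t".join(states))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cohort(path) -> Cohort:
    comments, rows = _split_comments(_read_text(path))
    if not rows:
        raise InputError(f"{path}: no data rows")
    sep = _sniff_sep(rows[0])
    df = pd.read_csv(
        _io.StringIO("\n".join(rows)), sep=sep, dtype=str, keep_default_na=False
    )
    df.columns = [c.strip() for c in df.columns]
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    locus_cols = [c for c in df.columns if c not in ("subject_id", "label")]
    if not locus_cols:
        raise InputError(f"{path}: no genotype columns")
    n = len(df)
    genotypes = np.empty((n, len(locus_cols)), dtype=int)
    for j, col in enumerate(locus_cols):
        raw = df[col].str.strip()
        missing = raw.isin(("NA", "", "nan"))
        vals = pd.to_numeric(raw.where(~missing, "0"), errors="coerce")
        bad = vals.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}: non-integer genotype {raw.iloc[i]!r} in column "
                f"{col!r}, data row {i + 1}"
            )
        col_vals = vals.astype(int).to_numpy()
        col_vals[missing.to_numpy()] = MISSING
        genotypes[:, j] = col_vals
    labels = df["label"].str.strip().to_numpy()
    # labels written as integers read back as ints when possible
    try:
        labels = labels.astype(int)
    except ValueError:
        pass
    return Cohort(
        ids=df["subject_id"].str.strip().to_numpy(),
        genotypes=genotypes,
        labels=labels,
        locus_ids=tuple(locus_cols),
        provenance=_parse_provenance(comments),
    )


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Provenance-stamped TSV with full-precision floats."""
    lines = _provenance_lines(provenance or {})
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(
        "\n".join(lines) + "\n" + buf.getvalue(), encoding="utf-8"
    )
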