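"""Readers and writers for the package's plain-text interchange formats.

Conventions: TSV for matrices and result tables, CSV for long-format plate
data; UTF-8, "." decimal separator, concentrations in µM throughout.
Censored potencies are written as ``>X`` and parsed back losslessly.
Output tables start with ``#`` comment lines naming the package version and
the configuration hash; readers skip ``#`` lines.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from ..dose_response import PlateExperiment
from ..go_frequency import TermFrequencyResult
from ..median_effect import CombinationIndexResult
from ..pk_context import CompoundMW, ExposureCoverage, PKRecord
from ..profile_clustering import LinkageTree, PotencyMatrix

__all__ = [
    "read_potency_table",
    "write_potency_table",
    "read_plate_csv",
    "write_plate_csv",
    "read_expression_table",
    "write_expression_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_mw_table",
    "read_pk_table",
    "write_ci_table",
    "write_associations",
    "write_go_table",
    "write_coverage_table",
    "write_merge_table",
    "write_newick",
]

_FLOAT_FMT = "%.6g"


def _write_header(fh, header_comment: str | None) -> None:
    if header_comment:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------- potency

def write_potency_table(
    pm: PotencyMatrix, path, header_comment: str | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        fh.write("compound\t" + "\t".join(pm.cell_lines) + "\n")
        for compound in pm.compounds:
            cells = []
            for line in pm.cell_lines:
                v = pm.values.at[compound, line]
                c = bool(pm.censored.at[compound, line])
                if pd.isna(v):
                    cells.append("")
                elif c:
                    cells.append(">" + _fmt(v))
                else:
                    cells.append(_fmt(v))
            fh.write(compound + "\t" + "\t".join(cells) + "\n")


def read_potency_table(path) -> PotencyMatrix:
    """Parse a compounds x lines TSV; ``>X`` censored, blank missing."""
    path = Path(path)
    rows: list[list[str]] = []
    with path.open(encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip("\n"):
                continue
            rows.append(raw.rstrip("\n").split("\t"))
    if not rows:
        raise ValueError(f"{path}: empty potency table")
    header = rows[0]
    lines = header[1:]
    compounds, values, censored = [], [], []
    for ri, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(f"{path}:{ri}: expected {len(header)} columns, got {len(row)}")
        compounds.append(row[0])
        vals, cens = [], []
        for ci, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            try:
                if cell == "":
                    vals.append(np.nan)
                    cens.append(False)
                elif cell.startswith(">"):
                    vals.append(float(cell[1:]))
                    cens.append(True)
                else:
                    vals.append(float(cell))
                    cens.append(False)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed cell at row {ri}, column {ci}: {cell!r}"
                ) from exc
        values.append(vals)
        censored.append(cens)
    vdf = pd.DataFrame(values, index=compounds, columns=lines, dtype=float)
    cdf = pd.DataFrame(censored, index=compounds, columns=lines, dtype=bool)
    return PotencyMatrix(values=vdf, censored=cdf)


# ----------------------------------------------------------------- plates

_PLATE_COLS = ["compound", "cell_line", "experiment", "conc_uM", "replicate", "signal", "is_control"]


def write_plate_csv(plates: list[PlateExperiment], path, experiment_ids=None) -> None:
    """Long-format plate CSV; one row per well."""
    path = Path(path)
    if experiment_ids is None:
        experiment_ids = [1] * len(plates)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_PLATE_COLS)
        for p, exp in zip(plates, experiment_ids):
            for ci, conc in enumerate(p.concentrations):
                for ri in range(p.signals.shape[1]):
                    w.writerow(
                        [p.compound, p.cell_line, exp, _fmt(conc), ri + 1,
                         _fmt(p.signals[ci, ri]), 0]
                    )
            for wi, sig in enumerate(p.control_signals):
                w.writerow([p.compound, p.cell_line, exp, "", wi + 1, _fmt(sig), 1])


def read_plate_csv(path) -> list[PlateExperiment]:
    """Group long-format rows into PlateExperiments per compound x line x experiment."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _PLATE_COLS if c not in df.columns and c != "experiment"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "experiment" not in df.columns:
        df["experiment"] = 1
    plates = []
    for (compound, line, exp), grp in df.groupby(
        ["compound", "cell_line", "experiment"], sort=True
    ):
        ctrl = grp[grp["is_control"] == 1]
        trt = grp[grp["is_control"] == 0].copy()
        if trt.empty:
            raise ValueError(f"{path}: no treated wells for {compound}/{line}")
        trt["conc_uM"] = trt["conc_uM"].astype(float)
        pivot = trt.pivot_table(
            index="conc_uM", columns="replicate", values="signal", aggfunc="first"
        ).sort_index()
        if pivot.isna().any().any():
            raise ValueError(
                f"{path}: ragged replicate structure for {compound}/{line}"
            )
        plates.append(
            PlateExperiment(
                compound=str(compound),
                cell_line=str(line),
                concentrations=pivot.index.to_numpy(dtype=float),
                signals=pivot.to_numpy(dtype=float),
                control_signals=ctrl["signal"].to_numpy(dtype=float),
            )
        )
    return plates


# ------------------------------------------------------------- expression

def write_expression_table(em: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        em.to_csv(fh, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", comment="#", index_col="gene").astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated cell-line ids")
    return df


# ------------------------------------------------------------- annotation

def write_annotation_table(ann: dict[str, set[str]], path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        fh.write("gene\tterm\n")
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_annotation_table(path) -> dict[str, set[str]]:
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    ann: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        ann.setdefault(str(gene), set()).add(str(term))
    return ann


# --------------------------------------------------------------------- pk

def read_mw_table(path) -> dict[str, CompoundMW]:
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    return {
        str(r["compound"]): CompoundMW(str(r["compound"]), float(r["mw_g_mol"]))
        for _, r in df.iterrows()
    }


def read_pk_table(path) -> list[PKRecord]:
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    out = []
    for _, r in df.iterrows():
        out.append(
            PKRecord(
                compound=str(r["compound"]),
                dose=str(r.get("dose", "")),
                cmax_ng_ml=None if pd.isna(r.get("cmax_ng_ml")) else float(r["cmax_ng_ml"]),
                auc_ng_h_ml=None if pd.isna(r.get("auc_ng_h_ml")) else float(r["auc_ng_h_ml"]),
                half_life_h=None if pd.isna(r.get("half_life_h")) else float(r["half_life_h"]),
                source=str(r.get("source", "")),
            )
        )
    return out


# ---------------------------------------------------------- result tables

def write_ci_table(res: CombinationIndexResult, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        fh.write("fa\tD1\tD2\tDx1\tDx2\tCI_exclusive\tCI_nonexclusive\tclassification\n")
        for i in range(len(res.fa)):
            fh.write(
                "\t".join(
                    [_fmt(res.fa[i]), _fmt(res.d1[i]), _fmt(res.d2[i]),
                     _fmt(res.dx1[i]), _fmt(res.dx2[i]),
                     _fmt(res.ci_exclusive[i]), _fmt(res.ci_nonexclusive[i]),
                     res.classification[i]]
                ) + "\n"
            )


def write_associations(assocs, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        fh.write("gene\tcompound\tr\tp\tn\tdirection\n")
        for a in assocs:
            fh.write(
                f"{a.gene}\t{a.compound}\t{_fmt(a.r)}\t{_fmt(a.p)}\t{a.n}\t{a.direction}\n"
            )


def write_go_table(
    ranked: list[tuple[str, int]],
    freq: TermFrequencyResult,
    path,
    header_comment: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        fh.write(f"# n_hits={freq.n_hits} n_annotated={freq.n_annotated}\n")
        fh.write("term\tcount\tfraction_of_hits\n")
        for term, count in ranked:
            frac = count / freq.n_hits if freq.n_hits else 0.0
            fh.write(f"{term}\t{count}\t{_fmt(frac)}\n")


def write_coverage_table(coverages: list[ExposureCoverage], path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        fh.write("compound\tcmax_uM\tfraction_covered\tn_lines\n")
        for c in coverages:
            fh.write(
                f"{c.compound}\t{_fmt(c.cmax_uM)}\t{_fmt(c.fraction_covered)}\t{len(c.ratios)}\n"
            )


def write_merge_table(tree: LinkageTree, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, header_comment)
        fh.write("step\tcluster_a\tcluster_b\theight\tsize\n")
        for i, (a, b, h, size) in enumerate(tree.merges, start=1):
            fh.write(f"{i}\t{int(a)}\t{int(b)}\t{_fmt(h)}\t{int(size)}\n")


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + "\n", encoding="utf-8")
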