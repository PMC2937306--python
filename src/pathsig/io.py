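"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (first column probe id, header row of
sample ids) or GCT 1.2; annotations and truth tables as TSV; survival
tables as CSV; signatures as TSV with a commented header or as JSON; score
vectors as TSV plus a JSON provenance block; cluster results as CDT + GTR
files loadable by Java TreeView.  Every writer's output round-trips through
the matching reader value-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .preprocess import ClusterResult
from .projection import ScoreVector
from .signature import SignatureModel, SignaturePrior

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_survival",
    "write_survival",
    "read_signature",
    "write_signature",
    "write_scores",
    "read_scores",
    "write_treeview",
    "write_discordance",
    "write_km_curve",
]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "gct" if path.suffix.lower() == ".gct" else "tsv"


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique()
        raise ParseError(
            f"duplicate {what} id(s): {', '.join(map(str, dupes[:5]))}"
        )


def _parse_matrix_lines(lines, path, id_col: int, n_meta: int, start_line: int):
    """Parse tab-separated numeric rows; report bad cells with line numbers."""
    probe_ids = []
    rows = []
    for lineno, line in lines:
        parts = line.rstrip("\n").split("\t")
        probe_ids.append(parts[id_col])
        try:
            rows.append([float(v) for v in parts[n_meta:]])
        except ValueError:
            for j, v in enumerate(parts[n_meta:], start=n_meta):
                try:
                    float(v)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {v!r} in "
                        f"column {j + 1}"
                    ) from None
            raise
    return probe_ids, rows


def read_expression(path, format: str | None = None) -> pd.DataFrame:
    """Read a probes x samples log2 expression matrix (TSV or GCT 1.2)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text().splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    if fmt == "gct":
        if text[0].strip() != "#1.2":
            raise ParseError(f"{path}:1: expected '#1.2' version line")
        try:
            n_rows, n_cols = (int(v) for v in text[1].split("\t")[:2])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:2: malformed dimensions line") from None
        header = text[2].split("\t")
        sample_ids = header[2:]
        if len(sample_ids) != n_cols:
            raise ParseError(
                f"{path}: dimensions line declares {n_cols} samples, "
                f"header has {len(sample_ids)}"
            )
        body = [(i + 4, ln) for i, ln in enumerate(text[3:]) if ln.strip()]
        if len(body) != n_rows:
            raise ParseError(
                f"{path}: dimensions line declares {n_rows} rows, "
                f"found {len(body)}"
            )
        probe_ids, rows = _parse_matrix_lines(body, path, 0, 2, 4)
    else:
        header = text[0].split("\t")
        sample_ids = header[1:]
        body = [(i + 2, ln) for i, ln in enumerate(text[1:]) if ln.strip()]
        probe_ids, rows = _parse_matrix_lines(body, path, 0, 1, 2)
    _check_unique(probe_ids, "probe")
    _check_unique(sample_ids, "sample")
    for (lineno, _), row in zip(body, rows):
        if len(row) != len(sample_ids):
            raise ParseError(
                f"{path}:{lineno}: expected {len(sample_ids)} values, "
                f"found {len(row)}"
            )
    df = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    if not np.isfinite(df.to_numpy()).all():
        raise ParseError(f"{path}: matrix contains non-finite values")
    return df


def write_expression(df: pd.DataFrame, path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gct":
        with path.open("w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
            for probe, row in zip(df.index, df.to_numpy()):
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{probe}\t{probe}\t{vals}\n")
    else:
        out = df.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format=None)
    return path


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "arm" not in df.columns:
        raise ParseError(f"{path}: annotation needs an 'arm' column")
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    _check_unique(df.index, "sample")
    return df


def write_annotation(annot: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = annot.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    return path


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: survival table needs a {col!r} column")
    _check_unique(df.index, "sample")
    if (df["time"] < 0).any():
        raise ParseError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event flags must be 0 or 1")
    df["event"] = df["event"].astype(int)
    return df[["time", "event"]]


def write_survival(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = table[["time", "event"]].copy()
    out.index.name = "sample_id"
    out.to_csv(path)
    return path


def write_signature(model: SignatureModel, path, format: str = "tsv") -> Path:
    path = Path(path)
    if format == "json":
        payload = {
            "label": model.label,
            "prior": vars(model.prior) if model.prior else None,
            "probes": [
                {"probe_id": str(p), "pi": float(r["pi"]),
                 "beta": float(r["beta"]), "sigma2": float(r["sigma2"])}
                for p, r in model.table.iterrows()
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path
    with path.open("w") as fh:
        fh.write(f"# treatment: {model.label}\n")
        if model.prior is not None:
            pr = model.prior
            fh.write(
                f"# prior: rho={pr.rho} g={pr.g} nu0={pr.nu0} "
                f"s0_sq={pr.s0_sq}\n"
            )
        fh.write("probe_id\tpi\tbeta\tsigma2\n")
        for p, r in model.table.iterrows():
            fh.write(
                f"{p}\t{float(r['pi'])!r}\t{float(r['beta'])!r}\t"
                f"{float(r['sigma2'])!r}\n"
            )
    return path


def read_signature(path) -> SignatureModel:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        table = pd.DataFrame(payload["probes"]).set_index("probe_id")
        prior = SignaturePrior(**payload["prior"]) if payload["prior"] else None
        return SignatureModel(payload["label"], table[["pi", "beta", "sigma2"]],
                              prior)
    label = ""
    prior = None
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# treatment:"):
                label = line.split(":", 1)[1].strip()
            elif line.startswith("# prior:"):
                kv = dict(
                    item.split("=") for item in line.split(":", 1)[1].split()
                )
                prior = SignaturePrior(**{k: float(v) for k, v in kv.items()})
            elif line.startswith("#") or line.startswith("probe_id"):
                continue
            elif line.strip():
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ParseError(
                        f"{path}:{lineno}: expected 4 fields, got {len(parts)}"
                    )
                try:
                    rows.append(
                        (parts[0], float(parts[1]), float(parts[2]),
                         float(parts[3]))
                    )
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric signature value"
                    ) from None
    table = pd.DataFrame(
        rows, columns=["probe_id", "pi", "beta", "sigma2"]
    ).set_index("probe_id")
    return SignatureModel(label, table, prior)


def write_scores(sv: ScoreVector, path) -> Path:
    """TSV of (sample, score) plus a .json provenance sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tscore\n")
        for s, v in sv.scores.items():
            fh.write(f"{s}\t{float(v)!r}\n")
    prov = {
        "signature": sv.label,
        "weight": sv.weight,
        "centered": sv.centering is not None,
        "n_probes_used": len(sv.probes_used),
        "n_probes_dropped": sv.n_dropped,
        "probes_used": [str(p) for p in sv.probes_used],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(prov, indent=1)
    )
    return path


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "score" not in df.columns:
        raise ParseError(f"{path}: expected a 'score' column")
    _check_unique(df.index, "sample")
    return df["score"]


def write_discordance(result, path) -> Path:
    path = Path(path)
    out = result.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    return path


def write_km_curve(curve, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time\tsurvival\tat_risk\tevents\n")
        for t, s, r, d in zip(
            curve.times, curve.survival, curve.at_risk, curve.n_events
        ):
            fh.write(f"{float(t)!r}\t{float(s)!r}\t{int(r)}\t{int(d)}\n")
    return path


def write_treeview(
    cluster: ClusterResult, matrix: pd.DataFrame, base_path
) -> tuple[Path, Path]:
    """Export a row dendrogram as CDT + GTR files for Java TreeView.

    The CDT carries the clustered matrix in leaf order with the standard
    GID / probe-id / NAME / GWEIGHT columns; the GTR lists merges bottom-up
    with a similarity score of 1 - merge height (the correlation-similarity
    convention of the Cluster 3.0 family).
    """
    base = Path(base_path)
    cdt_path = base.with_suffix(".cdt")
    gtr_path = base.with_suffix(".gtr")
    n = matrix.shape[0]
    gid = [f"GENE{i}X" for i in range(n)]
    with cdt_path.open("w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" +
                 "\t".join(map(str, matrix.columns)) + "\n")
        for i in cluster.leaf_order:
            probe = matrix.index[i]
            vals = "\t".join(repr(float(v)) for v in matrix.iloc[i])
            fh.write(f"{gid[i]}\t{probe}\t{probe}\t1.0\t{vals}\n")
    with gtr_path.open("w") as fh:
        for k, (a, b, height, _) in enumerate(cluster.linkage_matrix):
            left = gid[int(a)] if a < n else f"NODE{int(a) - n + 1}X"
            right = gid[int(b)] if b < n else f"NODE{int(b) - n + 1}X"
            fh.write(f"NODE{k + 1}X\t{left}\t{right}\t{1.0 - float(height)!r}\n")
    return cdt_path, gtr_path
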