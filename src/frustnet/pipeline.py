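"""End-to-end pipeline orchestration and on-disk formats.

The runner executes the full analysis on a directory of per-subject inputs:
truncate time series to the cohort's shortest scan, correlate, binarize to
a signed network (optionally thresholded), split polarities, count the
triad census, measure negative-subnetwork topology, assemble the tidy
feature table and run the stagewise statistics.  It can also start from
precomputed signed networks (e.g. a deposited benchmark archive), in which
case no random state is touched.

On-disk conventions (all plain text):

* time series: CSV, one row per region, first column ``region``, remaining
  columns the timepoints in order;
* dense signed adjacency: CSV with region labels as header row and index
  column, entries in {+1, -1, 0};
* signed edge list: TSV with comment header lines carrying ``n_nodes`` and
  the label order, then 0-based ``i  j  sign`` rows (i < j);
* cohort metadata: CSV with ``subject_id, age, sex[, stage]``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import census as _census
from . import topology as _topology
from .network import (
    RegionalTimeSeries,
    SignedNetwork,
    binarize_signs,
    negative_link_density,
    pearson_connectivity,
    split_subnetworks,
    truncate_to_common_length,
)
from .stats import (
    STAGES,
    assign_stage,
    dunn_posthoc,
    fit_poly_and_select,
    interaction_test,
    kruskal_wallis,
    mann_whitney,
    normality_gate,
)
from .synthetic import CohortSubject, GroundTruth, SyntheticCohortSpec

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "import_signed_networks",
    "write_signed_network",
    "read_signed_network",
    "write_timeseries",
    "read_timeseries",
    "write_cohort",
    "compute_feature_table",
    "compare_features",
]

logger = logging.getLogger("frustnet")

FEATURE_COLUMNS = (
    "frustration",
    "n_ppn",
    "n_nnn",
    "neg_density",
    "tmh",
    "aspl",
    "transitivity",
)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_timeseries(ts: RegionalTimeSeries, path: Path | str) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        ts.values, index=pd.Index(ts.region_labels, name="region")
    )
    frame.columns = [f"t{k}" for k in range(ts.n_timepoints)]
    frame.to_csv(path)


def read_timeseries(path: Path | str, subject_id: str | None = None) -> RegionalTimeSeries:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return RegionalTimeSeries(
        frame.to_numpy(dtype=float),
        tuple(str(r) for r in frame.index),
        subject_id or path.stem,
    )


def write_signed_network(net: SignedNetwork, path: Path | str, fmt: str = "dense") -> None:
    path = Path(path)
    if fmt == "dense":
        frame = pd.DataFrame(
            net.adjacency,
            index=pd.Index(net.region_labels, name="region"),
            columns=net.region_labels,
        )
        frame.to_csv(path)
    elif fmt == "edgelist":
        iu = np.triu_indices(net.n_nodes, k=1)
        present = net.adjacency[iu] != 0
        with open(path, "w") as fh:
            fh.write("# signed edge list; 0-based node indices; i < j\n")
            fh.write(f"# n_nodes={net.n_nodes}\n")
            fh.write("# labels=" + ",".join(net.region_labels) + "\n")
            fh.write("i\tj\tsign\n")
            for i, j, s in zip(
                iu[0][present], iu[1][present], net.adjacency[iu][present]
            ):
                fh.write(f"{i}\t{j}\t{int(s)}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_signed_network(path: Path | str, subject_id: str | None = None) -> SignedNetwork:
    path = Path(path)
    sid = subject_id or path.stem
    if path.suffix.lower() in (".tsv", ".tab", ".edges"):
        n_nodes = None
        labels: tuple[str, ...] = ()
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("i\t"):
                    continue
                if line.startswith("#"):
                    body = line.lstrip("# ")
                    if body.startswith("n_nodes="):
                        n_nodes = int(body.split("=", 1)[1])
                    elif body.startswith("labels="):
                        labels = tuple(body.split("=", 1)[1].split(","))
                    continue
                i, j, s = line.split("\t")
                rows.append((int(i), int(j), int(s)))
        if n_nodes is None:
            n_nodes = 1 + max(max(i, j) for i, j, _ in rows) if rows else 0
        adjacency = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for i, j, s in rows:
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"{path}: edge ({i}, {j}) outside n_nodes={n_nodes}")
            adjacency[i, j] = s
            adjacency[j, i] = s
        return SignedNetwork(adjacency, labels, provenance={"subject_id": sid})
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy()
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: dense adjacency must be square, got {values.shape}")
    try:
        return SignedNetwork(
            values,
            tuple(str(r) for r in frame.index),
            provenance={"subject_id": sid},
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def import_signed_networks(
    path: Path | str, pattern: str = "*"
) -> dict[str, SignedNetwork]:
    """Load and validate a directory of signed networks (dense or edge list)."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"network directory not found: {path}")
    nets: dict[str, SignedNetwork] = {}
    for file in sorted(path.glob(pattern)):
        if file.suffix.lower() not in (".csv", ".tsv", ".tab", ".edges"):
            continue
        nets[file.stem] = read_signed_network(file)
    if not nets:
        raise FileNotFoundError(f"no network files found under {path}")
    shapes = {net.n_nodes for net in nets.values()}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent node counts across subjects: {sorted(shapes)}")
    return nets


def write_cohort(
    subjects: Sequence[CohortSubject] | Sequence[tuple[RegionalTimeSeries, GroundTruth]],
    out_dir: Path | str,
    spec: SyntheticCohortSpec | None = None,
    fmt: str = "dense",
) -> Path:
    """Write a generated cohort: per-subject files + metadata + truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truths = []
    for item in subjects:
        if isinstance(item, CohortSubject):
            sub_dir = out_dir / "networks"
            sub_dir.mkdir(exist_ok=True)
            ext = ".csv" if fmt == "dense" else ".tsv"
            write_signed_network(item.network, sub_dir / f"{item.subject_id}{ext}", fmt)
            sid, age, sex, stage, truth = (
                item.subject_id, item.age, item.sex, item.stage, item.truth,
            )
        else:
            ts, truth = item
            sub_dir = out_dir / "timeseries"
            sub_dir.mkdir(exist_ok=True)
            write_timeseries(ts, sub_dir / f"{ts.subject_id}.csv")
            sid, age, sex, stage = truth.subject_id, truth.age, truth.sex, truth.stage
        meta_rows.append(
            {"subject_id": sid, "age": age, "sex": sex, "stage": stage}
        )
        truths.append(asdict(truth))
    pd.DataFrame(meta_rows).to_csv(out_dir / "metadata.csv", index=False)
    sidecar: dict[str, object] = {"ground_truth": truths}
    if spec is not None:
        spec_dict = asdict(spec)
        spec_dict["n_subjects_per_stage"] = dict(spec.n_subjects_per_stage)
        sidecar["spec"] = spec_dict
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out_dir


# ---------------------------------------------------------------------------
# feature computation
# ---------------------------------------------------------------------------

def subject_features(net: SignedNetwork, subject_id: str) -> dict[str, object]:
    """Census + negative-subnetwork topology for one subject."""
    cen = _census.census_trace(net)
    row: dict[str, object] = {
        "subject_id": subject_id,
        "n_regions": net.n_nodes,
        "n_edges": net.n_edges,
        "n_neg_edges": net.n_negative_edges,
        "neg_density": negative_link_density(net),
        **cen.as_dict(),
        "frustration_fraction": cen.frustration_fraction,
        "frustration": cen.n_frustrated,
    }
    _, neg = split_subnetworks(net)
    if neg.n_edges == 0:
        warnings.warn(f"{subject_id}: negative subnetwork is edgeless", stacklevel=2)
        row.update(tmh=np.nan, aspl=np.nan, efficiency=np.nan,
                   transitivity=np.nan, n_excluded_pairs=np.nan)
        return row
    row["tmh"] = _topology.tmh(neg)
    sp = _topology.aspl(neg)
    row["aspl"] = sp.value
    row["efficiency"] = 1.0 / sp.value
    row["n_excluded_pairs"] = sp.n_excluded_pairs
    if sp.n_excluded_pairs:
        warnings.warn(
            f"{subject_id}: negative subnetwork fragmented "
            f"({sp.n_excluded_pairs} disconnected pairs excluded from ASPL)",
            stacklevel=2,
        )
    try:
        row["transitivity"] = _topology.transitivity(neg)
    except ValueError:
        row["transitivity"] = np.nan
    return row


def compute_feature_table(
    networks: Mapping[str, SignedNetwork], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Tidy per-subject feature table: metadata + census + topology."""
    metadata = metadata.copy()
    if "stage" not in metadata.columns or metadata["stage"].isna().any():
        metadata["stage"] = metadata["age"].map(assign_stage)
    missing = set(metadata["subject_id"].astype(str)) - set(networks)
    extra = set(networks) - set(metadata["subject_id"].astype(str))
    if missing:
        raise ValueError(f"metadata subjects without network files: {sorted(missing)}")
    if extra:
        raise ValueError(f"network files without metadata rows: {sorted(extra)}")
    rows = [subject_features(networks[sid], sid) for sid in metadata["subject_id"].astype(str)]
    features = pd.DataFrame(rows)
    return metadata.merge(features, on="subject_id", validate="one_to_one")


# ---------------------------------------------------------------------------
# statistics report
# ---------------------------------------------------------------------------

def compare_features(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURE_COLUMNS,
    alpha: float = 0.05,
) -> dict[str, object]:
    """Stagewise comparison report for each feature, plus sex and model tests.

    For every feature: Shapiro-Wilk gate, Kruskal-Wallis across stages and a
    Dunn/BH post hoc table.  Additionally: Mann-Whitney sex comparisons of
    frustration (pooled and per stage), pooled and stagewise polynomial model
    selection of frustration on negative density, and the stage x density
    interaction test.
    """
    stages_present = [s for s in STAGES if s in set(table["stage"])]
    if len(stages_present) < 2:
        raise ValueError("stagewise comparison needs at least 2 stages")
    report: dict[str, object] = {"alpha": alpha, "stages": stages_present}
    per_feature: dict[str, object] = {}
    for feat in features:
        sub = table.dropna(subset=[feat])
        groups = {s: sub.loc[sub["stage"] == s, feat].to_numpy() for s in stages_present}
        gate = normality_gate(groups, alpha=alpha)
        kw = kruskal_wallis(groups)
        entry: dict[str, object] = {
            "shapiro_p_by_stage": dict(gate.p_by_group),
            "nonparametric": gate.nonparametric,
            "kruskal_wallis": {
                "H": kw.statistic,
                "df": kw.df,
                "p": kw.pvalue,
                "group_sizes": list(kw.group_sizes),
            },
            "median_by_stage": {s: float(np.median(v)) for s, v in groups.items()},
        }
        if len(stages_present) >= 3:
            entry["dunn"] = dunn_posthoc(groups, alpha=alpha).to_dict("records")
        per_feature[feat] = entry
    report["features"] = per_feature

    # sex contrasts on frustration
    sex_block: dict[str, object] = {}
    males = table.loc[table["sex"] == "male", "frustration"]
    females = table.loc[table["sex"] == "female", "frustration"]
    if len(males) and len(females):
        res = mann_whitney(males, females)
        sex_block["pooled"] = {"U": res.statistic, "p": res.pvalue, **dict(res.extra)}
        by_stage = {}
        for s in stages_present:
            sub = table[table["stage"] == s]
            m = sub.loc[sub["sex"] == "male", "frustration"]
            f = sub.loc[sub["sex"] == "female", "frustration"]
            if len(m) >= 2 and len(f) >= 2:
                r = mann_whitney(m, f)
                by_stage[s] = {"U": r.statistic, "p": r.pvalue, **dict(r.extra)}
        sex_block["by_stage"] = by_stage
    report["sex_frustration"] = sex_block

    # frustration ~ negative density: pooled model selection + interaction
    try:
        pooled = fit_poly_and_select(table)
        report["model_selection"] = {
            "selected_degree": pooled.selected_degree,
            "coefficients": {
                str(d): list(map(float, c)) for d, c in pooled.coefficients.items()
            },
            "rss": {str(d): float(v) for d, v in pooled.rss.items()},
            "f_tests": {
                f"{a}v{b}": {"F": f, "p": p}
                for (a, b), (f, p) in pooled.f_tests.items()
            },
        }
        inter = interaction_test(table, degree=pooled.selected_degree)
        report["interaction"] = {
            "F": inter.statistic,
            "df": list(inter.df),
            "p": inter.pvalue,
        }
    except ValueError as err:
        report["model_selection"] = {"error": str(err)}
    return report


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of an end-to-end run."""

    input_dir: str
    metadata: str
    out_dir: str
    mode: str = "timeseries"  # or "networks"
    tau: float | None = None
    bin_width: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("timeseries", "networks"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class RunManifest:
    """Record of a pipeline run: config, outputs, checksums, warnings."""

    config: Mapping[str, object]
    version: str
    started: float
    finished: float
    outputs: Mapping[str, str]  # path -> sha256
    warnings: tuple[str, ...]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all artifacts plus a manifest."""
    from . import __version__

    started = time.time()
    input_dir = Path(config.input_dir)
    meta_path = Path(config.metadata)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    if not meta_path.is_file():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    metadata = pd.read_csv(meta_path, dtype={"subject_id": str})

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if config.mode == "timeseries":
            series = []
            for sid in metadata["subject_id"]:
                candidates = [input_dir / f"{sid}.csv", input_dir / f"{sid}.tsv"]
                file = next((c for c in candidates if c.is_file()), None)
                if file is None:
                    raise FileNotFoundError(
                        f"no time-series file for subject {sid!r} under {input_dir}"
                    )
                series.append(read_timeseries(file, sid))
            series = truncate_to_common_length(series)
            networks = {
                ts.subject_id: binarize_signs(pearson_connectivity(ts), config.tau)
                for ts in series
            }
        else:
            networks = import_signed_networks(input_dir)
        table = compute_feature_table(networks, metadata)
        report = compare_features(table, alpha=config.alpha)
        captured = [str(w.message) for w in wlist]

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features_path = out_dir / "features.csv"
    table.to_csv(features_path, index=False, float_format="%.10g")
    report_path = out_dir / "statistics.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    kw_rows = [
        {
            "feature": feat,
            "H": entry["kruskal_wallis"]["H"],
            "df": entry["kruskal_wallis"]["df"],
            "p": entry["kruskal_wallis"]["p"],
        }
        for feat, entry in report["features"].items()
    ]
    kw_path = out_dir / "stage_comparisons.csv"
    pd.DataFrame(kw_rows).to_csv(kw_path, index=False)

    outputs = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in (features_path, report_path, kw_path)
    }
    manifest = RunManifest(
        config={**asdict(config)},
        version=__version__,
        started=started,
        finished=time.time(),
        outputs=outputs,
        warnings=tuple(captured),
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=1, default=str)
    return manifest
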