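"""Readers, writers and run configuration.

All tabular formats are plain text: expression as gene-by-sample TSV,
signatures as two-column TSV (gene, weight) or single-set GMT, clinical
tables and scores as CSV. Writers prepend ``#``-comment header lines
carrying the config hash and seed, so every stochastic output records its
provenance; readers skip such lines.

Gene identifiers are opaque case-sensitive strings — no symbol/ID mapping
happens here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clinical import ClinicalCohort
from .containers import DrugSignature, ExpressionMatrix, NormalizationState
from .response import DoseResponsePanel, GrowthCurveSet

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_signature",
    "write_signature",
    "read_clinical",
    "write_clinical",
    "read_dose_response",
    "write_dose_response",
    "read_growth_curves",
    "write_growth_curves",
    "write_scores",
    "read_scores",
]

DEFAULT_SIGNATURE_SIZES = {"5FU": 39, "oxaliplatin": 277, "irinotecan": 25}


@dataclass
class RunConfig:
    """Run-level configuration recorded in every output."""

    seed: int = 0
    n_components: int = 12
    signature_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURE_SIZES))
    min_group_proportion: float = 0.10
    alpha: float = 0.05
    min_gene_overlap: float = 0.80
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.min_group_proportion < 0.5:
            raise ValueError("min_group_proportion must be in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for drug, n in self.signature_sizes.items():
            if n <= 0:
                raise ValueError(f"signature size for {drug!r} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"# chemosig config={self.digest()} seed={self.seed}"]


def _write_with_header(df: pd.DataFrame, path: str | Path, sep: str,
                       config: RunConfig | None, index: bool = True,
                       index_label: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        # %.17g guarantees lossless float round-trips
        df.to_csv(fh, sep=sep, index=index, index_label=index_label, float_format="%.17g")


# -- expression ---------------------------------------------------------------


def read_expression(
    path: str | Path,
    genes_in_rows: bool = True,
    state: NormalizationState | str = NormalizationState.RAW_COUNTS,
) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (header = sample ids, first column = gene ids).

    ``genes_in_rows=False`` transposes a sample-by-gene file on read.
    Duplicate identifiers and non-numeric cells are format errors naming the
    offending entry.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if not genes_in_rows:
        df = df.T
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValueError(f"duplicate gene identifiers: {', '.join(map(str, dup_genes))}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValueError(f"duplicate sample identifiers: {', '.join(map(str, dup_samples))}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        g = bad.any(axis=1).idxmax()
        s = bad.loc[g].idxmax()
        raise ValueError(
            f"non-numeric expression value {df.loc[g, s]!r} at gene {g!r}, sample {s!r}"
        )
    if numeric.isna().any().any():
        g = numeric.isna().any(axis=1).idxmax()
        raise ValueError(f"missing expression value in gene row {g!r}")
    # python float() is correctly rounded; pandas' fast parser can be 1 ulp off
    exact = df.map(float)
    return ExpressionMatrix(exact, NormalizationState(state))


def write_expression(
    em: ExpressionMatrix, path: str | Path, config: RunConfig | None = None
) -> None:
    _write_with_header(em.data, path, sep="\t", config=config, index_label="gene")


# -- signatures ---------------------------------------------------------------


def read_signature(path: str | Path, drug: str | None = None) -> DrugSignature:
    """Read a signature from two-column TSV (gene, weight) or GMT.

    GMT lines (``name<TAB>description<TAB>gene...``) carry no weights; every
    gene gets weight 1. Only single-set GMT files are accepted.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty signature file: {path}")

    first = lines[0].split("\t")
    is_gmt = path.suffix.lower() == ".gmt" or len(first) > 2
    if is_gmt:
        if len(lines) > 1:
            raise ValueError("GMT signature file must contain exactly one gene set")
        name, _desc, *genes = lines[0].split("\t")
        if not genes:
            raise ValueError("GMT line contains no genes")
        return DrugSignature(drug=drug or name, gene_ids=genes, weights=np.ones(len(genes)))

    rows = []
    start = 0
    # tolerate a header row
    try:
        float(first[1])
    except (ValueError, IndexError):
        start = 1
    for ln in lines[start:]:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed signature line: {ln!r}")
        gene, w = parts
        try:
            wf = float(w)
        except ValueError as exc:
            raise ValueError(f"non-numeric weight {w!r} for gene {gene!r}") from exc
        if not np.isfinite(wf):
            raise ValueError(f"non-finite weight for gene {gene!r}")
        rows.append((gene, wf))
    genes = [g for g, _ in rows]
    return DrugSignature(
        drug=drug or path.stem,
        gene_ids=genes,
        weights=np.array([w for _, w in rows]),
    )


def write_signature(
    sig: DrugSignature, path: str | Path, config: RunConfig | None = None
) -> None:
    df = pd.DataFrame({"gene": sig.gene_ids, "weight": sig.weights})
    _write_with_header(df, path, sep="\t", config=config, index=False)


# -- clinical -----------------------------------------------------------------


def read_clinical(path: str | Path) -> ClinicalCohort:
    df = pd.read_csv(path, comment="#")
    return ClinicalCohort(df)


def write_clinical(
    cohort: ClinicalCohort, path: str | Path, config: RunConfig | None = None
) -> None:
    _write_with_header(cohort.data.reset_index(drop=True), path, sep=",",
                       config=config, index=False)


# -- preclinical response -----------------------------------------------------


def write_dose_response(
    panels: dict, path: str | Path, config: RunConfig | None = None
) -> None:
    """Long-form CSV: model_id, drug, dose, replicate, viability."""
    rows = []
    for (model_id, drug), panel in panels.items():
        n_rep = 0
        seen: dict[float, int] = {}
        for dose, viab in zip(panel.doses, panel.viability):
            rep = seen.get(dose, 0)
            seen[dose] = rep + 1
            rows.append((model_id, drug, dose, rep, viab))
    df = pd.DataFrame(rows, columns=["model_id", "drug", "dose", "replicate", "viability"])
    _write_with_header(df, path, sep=",", config=config, index=False)


def read_dose_response(path: str | Path) -> dict:
    df = pd.read_csv(path, comment="#")
    panels = {}
    for (model_id, drug), g in df.groupby(["model_id", "drug"], sort=False):
        panels[(model_id, drug)] = DoseResponsePanel(
            model_id=model_id, drug=drug,
            doses=g["dose"].to_numpy(float),
            viability=g["viability"].to_numpy(float),
        )
    return panels


def write_growth_curves(
    growth: dict, path: str | Path, config: RunConfig | None = None
) -> None:
    """Long-form CSV: pdx_id, drug, arm, mouse, day, volume."""
    rows = []
    for drug, per_pdx in growth.items():
        for pdx_id, (treated, control) in per_pdx.items():
            for gcs in (treated, control):
                for mouse, (days, vols) in gcs.series.items():
                    for d, v in zip(days, vols):
                        rows.append((pdx_id, drug, gcs.arm, mouse, d, v))
    df = pd.DataFrame(rows, columns=["pdx_id", "drug", "arm", "mouse", "day", "volume"])
    _write_with_header(df, path, sep=",", config=config, index=False)


def read_growth_curves(path: str | Path) -> dict:
    df = pd.read_csv(path, comment="#")
    growth: dict = {}
    for (drug, pdx_id), g in df.groupby(["drug", "pdx_id"], sort=False):
        arms = {}
        for arm, ga in g.groupby("arm", sort=False):
            series = {
                mouse: (gm["day"].to_numpy(float), gm["volume"].to_numpy(float))
                for mouse, gm in ga.groupby("mouse", sort=False)
            }
            arms[arm] = GrowthCurveSet(pdx_id=pdx_id, arm=arm, series=series)
        if set(arms) != {"treated", "control"}:
            raise ValueError(f"pdx {pdx_id!r}/{drug!r}: need both treated and control arms")
        growth.setdefault(drug, {})[pdx_id] = (arms["treated"], arms["control"])
    return growth


# -- scores -------------------------------------------------------------------


def write_scores(
    scores: pd.DataFrame | pd.Series, path: str | Path, config: RunConfig | None = None
) -> None:
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    _write_with_header(df, path, sep=",", config=config, index_label="sample")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)
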