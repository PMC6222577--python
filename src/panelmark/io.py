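"""Tabular input/output for every format the pipeline touches.

All on-disk formats are plain text: TSV with a header row, UTF-8, '.' decimal,
matching GEO series-matrix conventions for expression data.  The expression
matrix is probes x samples with the header row holding sample ids; sample
metadata travels in a companion TSV keyed by ``sample_id``.

Gene symbols are stored case-preserving (mouse ``Gpnmb`` vs human ``GPNMB``
is meaningful downstream).  Missing trait values are written as empty cells
and dropped pairwise by the correlation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

TREATMENT_ARMS = ("control", "treated")

#: Well-established HF plasma-biomarker transcripts used as the default
#: known-marker list when flagging candidate novelty.
DEFAULT_KNOWN_MARKERS = frozenset({"Nppb", "Timp1", "Lgals3", "Spp1"})


@dataclass
class ExpressionPanel:
    """A log2 expression matrix plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = probe ids, columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with columns ``strain``, ``treatment``
        (one of ``control``/``treated``) and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise SchemaError(f"duplicate probe ids: {list(dups)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise SchemaError("expression matrix contains non-finite values")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise SchemaError(f"samples without metadata: {missing}")
        bad = set(self.sample_meta["treatment"]) - set(TREATMENT_ARMS)
        if bad:
            raise SchemaError(f"unknown treatment arms: {sorted(bad)}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def arm_columns(self, arm: str) -> list[str]:
        """Sample ids belonging to a treatment arm, in matrix column order."""
        in_arm = set(self.sample_meta.index[self.sample_meta["treatment"] == arm])
        return [s for s in self.values.columns if s in in_arm]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionPanel):
            return NotImplemented
        return self.values.equals(other.values) and self.sample_meta.equals(
            other.sample_meta
        )


# ---------------------------------------------------------------------------
# expression matrix + metadata
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionPanel:
    """Read an expression TSV and its sample-metadata TSV into a panel.

    Column order of the matrix is preserved.  A sample present in the matrix
    but absent from the metadata is a schema error naming the sample; a
    non-numeric cell is a parse error naming its row and column.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    bad_cols = [c for c in values.columns if values[c].dtype == object]
    if bad_cols:
        col = bad_cols[0]
        parsed = pd.to_numeric(values[col], errors="coerce")
        probe = values.index[parsed.isna().to_numpy().argmax()]
        raise SchemaError(
            f"non-numeric cell at probe {probe!r}, sample {col!r} in {path}"
        )
    values.index.name = "probe_id"
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str}).set_index(
        "sample_id"
    )
    return ExpressionPanel(values=values, sample_meta=meta)


def write_expression(
    panel: ExpressionPanel, path: str | Path, meta_path: str | Path
) -> None:
    df = panel.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", lineterminator="\n")
    panel.sample_meta.rename_axis("sample_id").reset_index().to_csv(
        meta_path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# small tables: trait, annotation, human DE, cohort
# ---------------------------------------------------------------------------

def read_trait(path: str | Path) -> pd.DataFrame:
    """Per-strain quantitative trait change (``strain``, ``trait_delta``)."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    _require(df, ["strain", "trait_delta"], path)
    if df["strain"].duplicated().any():
        raise SchemaError(f"duplicate strain rows in {path}")
    return df


def write_trait(trait: pd.DataFrame, path: str | Path) -> None:
    trait.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Probe annotation (``probe_id``, ``symbol``, ``species``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["probe_id", "symbol"], path)
    if df["probe_id"].duplicated().any():
        raise SchemaError(f"duplicate probe ids in annotation {path}")
    return df


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_human_de(path: str | Path) -> pd.DataFrame:
    """Human DE summary table (``symbol``, ``logFC``, ``p_value``)."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    _require(df, ["symbol", "p_value"], path)
    p = df["p_value"].dropna()
    if ((p < 0) | (p > 1)).any():
        raise SchemaError(f"p_value outside [0, 1] in {path}")
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Subject-level case-control table (CSV).

    Required columns: ``subject_id``, ``biomarker_ng_ml``, ``hf_status``;
    covariates and ``probnp`` are optional.
    """
    df = pd.read_csv(path)
    _require(df, ["subject_id", "biomarker_ng_ml", "hf_status"], path)
    if df["subject_id"].duplicated().any():
        raise SchemaError(f"duplicate subject ids in {path}")
    if (df["biomarker_ng_ml"] <= 0).any():
        raise SchemaError(f"non-positive biomarker values in {path}")
    if not df["hf_status"].isin([0, 1]).all():
        raise SchemaError(f"hf_status outside {{0,1}} in {path}")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, lineterminator="\n")


def _require(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# packaged fixtures (the printed top-DE and top-correlation tables)
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("panelmark.fixtures").joinpath(name)


def load_table1_fixture() -> pd.DataFrame:
    """Top ISO-vs-control differentially regulated probes (printed table).

    Columns ``probe_id symbol logFC AveExpr p_value p_adj``; the printed
    column headed "p-value" is stored as ``p_value`` and ``p_adj`` is left
    empty (the table legend and header disagree about which it is).
    """
    with resources.as_file(_fixture_path("table1_iso_de.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"probe_id": str, "symbol": str})


def load_table2_fixture() -> pd.DataFrame:
    """Top LVIDd-correlated probes (printed table): ``probe_id symbol cor p_value``."""
    with resources.as_file(_fixture_path("table2_lvidd_corr.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"probe_id": str, "symbol": str})


def load_human_de_fixture() -> pd.DataFrame:
    """Quoted human failing-vs-non-failing DE values for the four discussed genes.

    NPPB's fold change was not reported (only its non-significant p), so its
    ``logFC`` is NaN.
    """
    with resources.as_file(_fixture_path("human_hf_de.tsv")) as p:
        return read_human_de(p)


# ---------------------------------------------------------------------------
# optional GEO series-matrix reader (for real-accession replication)
# ---------------------------------------------------------------------------

def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Parse the expression block of a GEO series-matrix file.

    Reads the table between the ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` markers; index = probe ids, columns = GSM
    sample accessions.  Metadata lines are not interpreted.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise SchemaError(f"{path}: series-matrix table markers not found") from None
    from io import StringIO

    block = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [c.strip('"') for c in df.columns]
    df.index.name = "probe_id"
    return df
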