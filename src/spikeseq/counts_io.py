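"""Plain-text I/O for count matrices, gene annotations and sample metadata.

The on-disk dialect is deliberately simple and mirrors the shape of published
supplementary tables for bacterial RNA-seq experiments:

* counts:      TSV, genes as rows, first column ``gene_id``, one header row of
               sample ids, integer read counts.
* annotation:  TSV with columns ``gene_id``, ``length_bp``, ``rna_class``,
               ``origin``.
* metadata:    TSV with columns ``sample_id``, ``time_min``, ``condition``,
               ``od_at_harvest`` and optionally ``is_outlier``.

A gene/sample pair absent from the counts file is an error, never an implicit
zero: a measured zero ("no reads") is distinct from missing data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RNA_CLASSES = frozenset(
    {
        "rRNA_16S",
        "rRNA_23S",
        "rRNA_5S",
        "tRNA",
        "mRNA",
        "sRNA",
        "other_ncRNA",
        "spike_in_feature",
    }
)
#: RNA classes removed when reducing a gene set to protein-coding transcripts.
NONCODING_CLASSES = frozenset(
    {"rRNA_16S", "rRNA_23S", "rRNA_5S", "tRNA", "sRNA", "other_ncRNA"}
)
RRNA_CLASSES = ("rRNA_16S", "rRNA_23S", "rRNA_5S")
ORIGINS = frozenset({"chromosome", "plasmid"})
CONDITIONS = frozenset({"steady_state", "starvation", "rifampicin"})

ANNOTATION_COLUMNS = ["length_bp", "rna_class", "origin"]
SAMPLE_COLUMNS = ["time_min", "condition", "od_at_harvest", "is_outlier"]


class ValidationError(ValueError):
    """Raised when counts, annotation and metadata are mutually inconsistent."""


def validate_annotation(annotation: pd.DataFrame) -> None:
    if annotation.index.name != "gene_id":
        raise ValidationError("annotation index must be named 'gene_id'")
    dup = annotation.index[annotation.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicated gene_id in annotation: {dup}")
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    lengths = annotation["length_bp"]
    if not np.issubdtype(lengths.dtype, np.integer):
        if not np.all(np.equal(np.mod(lengths, 1), 0)):
            raise ValidationError("length_bp must be integral")
    if (lengths < 1).any():
        bad = annotation.index[lengths < 1].tolist()
        raise ValidationError(f"length_bp < 1 for genes: {bad}")
    bad_class = set(annotation["rna_class"]) - RNA_CLASSES
    if bad_class:
        raise ValidationError(f"unknown rna_class values: {sorted(bad_class)}")
    bad_origin = set(annotation["origin"]) - ORIGINS
    if bad_origin:
        raise ValidationError(f"unknown origin values: {sorted(bad_origin)}")
    plasmid = annotation["origin"] == "plasmid"
    spike = annotation["rna_class"] == "spike_in_feature"
    if not plasmid.equals(spike):
        off = annotation.index[plasmid ^ spike].tolist()
        raise ValidationError(
            "origin=plasmid must coincide with rna_class=spike_in_feature; "
            f"offending genes: {off}"
        )


def validate_samples(samples: pd.DataFrame) -> None:
    if samples.index.name != "sample_id":
        raise ValidationError("sample metadata index must be named 'sample_id'")
    dup = samples.index[samples.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicated sample_id: {dup}")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample metadata missing columns: {missing}")
    bad_cond = set(samples["condition"]) - CONDITIONS
    if bad_cond:
        raise ValidationError(f"unknown condition values: {sorted(bad_cond)}")
    if (samples["od_at_harvest"] <= 0).any():
        raise ValidationError("od_at_harvest must be positive")
    steady = samples[samples["condition"] == "steady_state"]
    if (steady["time_min"] > 0).any():
        raise ValidationError("steady-state samples must carry time_min <= 0")
    starv = samples[samples["condition"] == "starvation"]["time_min"].to_numpy()
    if len(starv) >= 2 and not np.all(np.diff(starv) > 0):
        raise ValidationError(
            "time_min must be strictly increasing within the starvation series"
        )


@dataclasses.dataclass
class CountMatrix:
    """Raw integer read counts per gene per sample, with annotation and metadata.

    ``counts`` is genes x samples; the gene set must match ``annotation``
    exactly (no orphans in either direction) and the sample columns must match
    the metadata index.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        validate_annotation(self.annotation)
        validate_samples(self.samples)
        counts = self.counts
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicated gene_id in counts: {dup}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or not np.all(
                np.equal(np.mod(values, 1), 0)
            ):
                raise ValidationError("counts must be integers")
            self.counts = counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        unknown = counts.index.difference(self.annotation.index).tolist()
        if unknown:
            raise ValidationError(f"genes in counts absent from annotation: {unknown}")
        unannotated = self.annotation.index.difference(counts.index).tolist()
        if unannotated:
            raise ValidationError(f"annotated genes absent from counts: {unannotated}")
        if set(counts.columns) != set(self.samples.index):
            raise ValidationError(
                "sample ids in counts header do not match metadata: "
                f"counts={list(counts.columns)} metadata={list(self.samples.index)}"
            )
        # canonical internal form: metadata follows the counts header
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.samples = self.samples.loc[counts.columns]
        self.samples.index.name = "sample_id"
        self.annotation = self.annotation.loc[counts.index]

    # -- convenience views ------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def plasmid_features(self) -> pd.Index:
        return self.annotation.index[self.annotation["origin"] == "plasmid"]

    @property
    def chromosomal_genes(self) -> pd.Index:
        return self.annotation.index[self.annotation["origin"] == "chromosome"]

    @property
    def steady_samples(self) -> pd.Index:
        return self.samples.index[self.samples["condition"] == "steady_state"]

    @property
    def starvation_samples(self) -> pd.Index:
        return self.samples.index[self.samples["condition"] == "starvation"]

    def length_kb(self, genes: Iterable[str] | None = None) -> pd.Series:
        lengths = self.annotation["length_bp"] / 1000.0
        if genes is not None:
            lengths = lengths.loc[list(genes)]
        return lengths

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(), self.annotation.copy(), self.samples.copy()
        )


def _read_tsv(path: str | Path, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != index_col:
        raise ValidationError(
            f"{path}: first column must be '{index_col}', got '{df.columns[0]}'"
        )
    return df.set_index(index_col)


def read_counts(
    counts_path: str | Path,
    annotation_path: str | Path,
    meta_path: str | Path,
) -> CountMatrix:
    """Read and cross-validate the three TSV inputs into a :class:`CountMatrix`."""
    counts = _read_tsv(counts_path, "gene_id")
    for col in counts.columns:
        if not np.issubdtype(counts[col].dtype, np.number):
            raise ValidationError(f"non-numeric counts in sample column '{col}'")
    annotation = _read_tsv(annotation_path, "gene_id")
    samples = _read_tsv(meta_path, "sample_id")
    if "is_outlier" not in samples.columns:
        samples["is_outlier"] = False
    samples["is_outlier"] = samples["is_outlier"].astype(bool)
    samples["time_min"] = samples["time_min"].astype(float)
    samples["od_at_harvest"] = samples["od_at_harvest"].astype(float)
    return CountMatrix(counts, annotation, samples)


def write_counts(
    matrix: CountMatrix,
    counts_path: str | Path,
    annotation_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write the canonical TSV form; inverse of :func:`read_counts`."""
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.annotation.to_csv(annotation_path, sep="\t")
    samples = matrix.samples.copy()
    samples["is_outlier"] = samples["is_outlier"].astype(bool)
    samples.to_csv(meta_path, sep="\t")


def read_gff_lengths(gff_path: str | Path) -> dict[str, int]:
    """Feature lengths (end - start + 1, GFF3 1-based inclusive) keyed by ID.

    A duplicated identifier with conflicting coordinates is an error.
    """
    import gffutils

    path = Path(gff_path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    lengths: dict[str, int] = {}
    for feature in db.all_features():
        if feature.end < feature.start:
            raise ValidationError(
                f"feature {feature.id}: end ({feature.end}) < start ({feature.start})"
            )
        length = feature.end - feature.start + 1
        if feature.id in lengths and lengths[feature.id] != length:
            raise ValidationError(
                f"duplicated identifier with different coordinates: {feature.id}"
            )
        lengths[feature.id] = length
    return lengths


def annotation_from_lengths(
    lengths: Mapping[str, int],
    rna_class: Mapping[str, str] | str = "mRNA",
    origin: Mapping[str, str] | str = "chromosome",
) -> pd.DataFrame:
    """Assemble an annotation table from a gene_id -> length_bp mapping."""
    ids = list(lengths)
    df = pd.DataFrame(
        {
            "length_bp": [int(lengths[g]) for g in ids],
            "rna_class": [
                rna_class if isinstance(rna_class, str) else rna_class[g] for g in ids
            ],
            "origin": [
                origin if isinstance(origin, str) else origin[g] for g in ids
            ],
        },
        index=pd.Index(ids, name="gene_id"),
    )
    validate_annotation(df)
    return df
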