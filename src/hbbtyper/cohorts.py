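"""Bundled cohort fixtures and helpers for desk-scale reanalysis.

Two kinds of fixture ship with the package:

* printed call tables (``validation_calls.tsv``, ``discovery_calls.tsv``)
  — per-sample variant, depth, VAF and reported zygosity from the assay's
  clinical evaluation, with the comparator standard-test diagnosis.
  These let the zygosity classifier and diagnosis engine be re-run from
  the printed numbers alone;
* simulation cohort specs (``dbs_validation_cohort.tsv``,
  ``discovery_phase_cohort.tsv``) — diploid genotypes for the read
  simulator, used to exercise the full pipeline end to end.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import allele_catalog as ac
from .annotation import annotate, parse_hgvs_c
from .interpretation import ClassifiedCall, Diagnosis, SampleGenotype, diagnose
from .reference_model import LocusModel, bundled_locus
from .variant_caller import CallerConfig, VariantCall, classify_zygosity

__all__ = [
    "validation_calls_path",
    "discovery_calls_path",
    "dbs_cohort_path",
    "phase_cohort_path",
    "barcodes_path",
    "load_printed_calls",
    "genotype_from_printed",
    "diagnose_printed",
]


def _data(name: str) -> Path:
    return Path(resources.files("hbbtyper.data") / name)


def validation_calls_path() -> Path:
    return _data("validation_calls.tsv")


def discovery_calls_path() -> Path:
    return _data("discovery_calls.tsv")


def dbs_cohort_path() -> Path:
    return _data("dbs_validation_cohort.tsv")


def phase_cohort_path() -> Path:
    return _data("discovery_phase_cohort.tsv")


def barcodes_path() -> Path:
    return _data("barcodes24.tsv")


def load_printed_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["vaf"] = pd.to_numeric(df["vaf"], errors="coerce")
    return df


def genotype_from_printed(
    sample_id: str,
    rows: pd.DataFrame,
    model: LocusModel | None = None,
    catalog: list[ac.CatalogEntry] | None = None,
    config: CallerConfig = CallerConfig(),
) -> SampleGenotype:
    """Reconstruct a SampleGenotype from printed (variant, depth, VAF) rows,
    re-deriving zygosity from the VAF windows rather than trusting the
    printed genotype column."""
    model = model or bundled_locus()
    catalog = catalog if catalog is not None else ac.default_catalog()
    classified: list[ClassifiedCall] = []
    for _, row in rows.iterrows():
        variant = parse_hgvs_c(row["hgvs_c"], model)
        vaf = float(row["vaf"])
        depth = int(row["depth"])
        zyg = classify_zygosity(vaf, config)
        call = VariantCall(
            gpos=variant.gpos,
            ref=variant.ref,
            alt=variant.alt,
            depth=depth,
            alt_count=int(round(vaf * depth)),
            vaf=vaf,
            zygosity=zyg,
            filter="PASS" if depth >= config.min_depth and zyg != "ambiguous"
            else ("low_depth" if depth < config.min_depth else "ambiguous_vaf"),
        )
        ann = annotate(variant, model)
        klass, catalogued = ac.classify_annotation(catalog, ann)
        classified.append(ClassifiedCall(call, ann, klass, catalogued))
    return SampleGenotype(sample_id=sample_id, classified_calls=classified)


def diagnose_printed(
    df: pd.DataFrame,
    model: LocusModel | None = None,
    config: CallerConfig = CallerConfig(),
) -> tuple[list[Diagnosis], dict[str, str]]:
    """Diagnose every sample of a printed call table.

    Returns the diagnoses and the printed standard-test reference labels
    (column ``standard_diagnosis``) for concordance checking.
    """
    model = model or bundled_locus()
    diagnoses = []
    references: dict[str, str] = {}
    for sid, rows in df.groupby("sample_id", sort=False):
        geno = genotype_from_printed(sid, rows, model=model, config=config)
        diagnoses.append(diagnose(geno))
        if "standard_diagnosis" in rows.columns:
            references[sid] = rows["standard_diagnosis"].iloc[0]
    return diagnoses, references
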