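"""Readers and writers for the pipeline's tabular formats.

Text formats throughout: map as TSV, traits/covariates/peaks as CSV with the
individual id in the first column, dosages as HDF5 (or long CSV), thresholds
and truth as JSON.  Floats are written with a fixed %.10g format so reruns
with identical seeds are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from pleioscan.preprocess import TraitTable
from pleioscan.scan import QtlPeak, ThresholdSet
from pleioscan.simulate import FOUNDERS, FounderDosage, GeneticMap

FLOAT_FMT = "%.10g"


def write_map(gmap: GeneticMap, path) -> None:
    df = gmap.markers.reset_index()
    df.columns = ["marker", "chromosome", "pos_cM", "pos_Mbp"]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return GeneticMap(df.set_index("marker"))


def write_dosage_hdf5(dosage: FounderDosage, path) -> None:
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w", track_order=False) as fh:
        fh.create_dataset("dosage", data=dosage.dosage, track_times=False)
        fh.create_dataset("individuals", data=np.array(dosage.individuals, dtype=str_dt), track_times=False)
        fh.create_dataset("markers", data=np.array(dosage.markers, dtype=str_dt), track_times=False)
        fh.create_dataset("founders", data=np.array(dosage.founders, dtype=str_dt), track_times=False)


def read_dosage_hdf5(path) -> FounderDosage:
    with h5py.File(path, "r") as fh:
        return FounderDosage(
            individuals=[s.decode() for s in fh["individuals"][...]],
            markers=[s.decode() for s in fh["markers"][...]],
            dosage=fh["dosage"][...],
            founders=[s.decode() for s in fh["founders"][...]],
        )


def write_dosage_csv(dosage: FounderDosage, path) -> None:
    """Long format: individual, marker, then one column per founder."""
    n, m, _ = dosage.dosage.shape
    df = pd.DataFrame(
        dosage.dosage.reshape(n * m, 8),
        columns=[f"dosage_{f}" for f in dosage.founders],
    )
    df.insert(0, "marker", np.tile(dosage.markers, n))
    df.insert(0, "individual", np.repeat(dosage.individuals, m))
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_counts(path, sep: str | None = None, features_in_rows: bool | None = None) -> pd.DataFrame:
    """Count table from CSV/TSV, returned as individuals x features.

    Orientation is autodetected when ``features_in_rows`` is None: a header
    flag cell of ``#OTU ID`` / ``feature`` marks features-in-rows (the common
    QIIME export layout); otherwise rows are taken as individuals.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment=None)
    if features_in_rows is None:
        flag = str(df.index.name or "").strip().lower()
        features_in_rows = flag in ("#otu id", "otu id", "feature", "feature id", "esv")
    return df.T if features_in_rows else df


def read_biom_json(path) -> tuple[pd.DataFrame, pd.Series]:
    """BIOM v1 (JSON) table -> (individuals x features counts, taxonomy).

    Supports dense and sparse matrix encodings; taxonomy is joined from the
    per-observation metadata when present.
    """
    with open(path) as fh:
        biom = json.load(fh)
    features = [r["id"] for r in biom["rows"]]
    samples = [c["id"] for c in biom["columns"]]
    shape = tuple(biom["shape"])
    mat = np.zeros(shape)
    if biom.get("matrix_type") == "sparse":
        for i, j, v in biom["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(biom["data"])
    counts = pd.DataFrame(mat.T, index=samples, columns=features)
    tax = {}
    for r in biom["rows"]:
        md = r.get("metadata") or {}
        lineage = md.get("taxonomy")
        if lineage is not None:
            tax[r["id"]] = ";".join(lineage) if isinstance(lineage, list) else str(lineage)
    return counts, pd.Series(tax, name="taxonomy")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_trait_table(table: TraitTable, path, sidecar_path=None) -> None:
    """Trait CSV plus a sidecar JSON recording class and transform state."""
    write_table(table.values, path)
    if sidecar_path is None:
        sidecar_path = Path(path).with_suffix(".meta.json")
    with open(sidecar_path, "w") as fh:
        json.dump(
            {"trait_class": table.trait_class, "transform": table.transform},
            fh, indent=2, sort_keys=True,
        )


def read_trait_table(path, sidecar_path=None) -> TraitTable:
    values = read_table(path)
    if sidecar_path is None:
        sidecar_path = Path(path).with_suffix(".meta.json")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return TraitTable(values, meta["trait_class"], meta["transform"])


def peaks_to_frame(peaks: list[QtlPeak]) -> pd.DataFrame:
    cols = ["trait", "trait_class", "chr", "pos_Mbp", "pos_cM", "lod", "ci_lo", "ci_hi"] + [
        f"coef_{f}" for f in FOUNDERS
    ]
    rows = []
    for p in peaks:
        coefs = p.coefs if p.coefs is not None else [np.nan] * 8
        rows.append(
            [p.trait, p.trait_class, p.chromosome, p.pos_Mbp, p.pos_cM, p.lod, p.ci_lo, p.ci_hi]
            + list(coefs)
        )
    return pd.DataFrame(rows, columns=cols)


def write_peaks(peaks: list[QtlPeak], path) -> None:
    peaks_to_frame(peaks).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_scans_long(scans: dict[str, pd.Series], path) -> None:
    """Long CSV (trait, marker, lod) over all scanned traits."""
    frames = [
        pd.DataFrame({"trait": name, "marker": s.index, "lod": s.to_numpy()})
        for name, s in scans.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_scans_long(path) -> dict[str, pd.Series]:
    df = pd.read_csv(path)
    return {
        name: sub.set_index("marker")["lod"]
        for name, sub in df.groupby("trait", sort=False)
    }


def write_thresholds(ts: ThresholdSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "thresholds": {str(a): v for a, v in ts.thresholds.items()},
                "n_perm": ts.n_perm,
                "pooled": ts.pooled,
            },
            fh, indent=2, sort_keys=True,
        )


def read_thresholds(path) -> ThresholdSet:
    with open(path) as fh:
        d = json.load(fh)
    return ThresholdSet({float(a): v for a, v in d["thresholds"].items()}, d["n_perm"], d["pooled"])
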