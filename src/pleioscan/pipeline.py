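"""Pipeline orchestration: simulate -> preprocess -> scan -> permute ->
peaks -> comap -> pleiotropy -> mediation -> report.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be rerun standalone.  A manifest records the seeds,
thresholds actually applied, and SHA-256 hashes of every output file;
identical configs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pleioscan import io as pio
from pleioscan.comap import comap_table, find_overlaps, spearman_bh_screen
from pleioscan.mediation import bidirectional_report
from pleioscan.pleiotropy import bootstrap_pvalue
from pleioscan.preprocess import prepare_metabolites, prepare_microbial
from pleioscan.scan import (
    compute_kinship_loco,
    genome_scan,
    peaks_for_trait,
    permutation_thresholds,
)
from pleioscan.simulate import (
    PairSpec,
    TraitSpec,
    simulate_covariates,
    simulate_do_genomes,
    simulate_map,
    simulate_taxonomy,
    simulate_traits,
)

log = logging.getLogger("pleioscan")

STAGES = ["simulate", "preprocess", "scan", "permute", "peaks", "comap", "pleio", "mediate", "report"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "pleioscan_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # synthetic population
    n_individuals: int = 200
    n_chromosomes: int = 5
    markers_per_chr: int = 50
    chr_length_cM: float = 90.0
    cM_per_Mbp: float = 2.0
    switch_density_per_cM: float = 0.2
    # background traits
    n_microbial: int = 6
    n_metabolite: int = 5
    qtl_var: float = 0.25
    h2: float = 0.3
    prevalence: float = 0.9
    planted_pairs: list[dict] = field(default_factory=list)
    # preprocessing
    min_prevalence: float = 0.2
    css_quantile: float = 0.5
    css_scale: float = 1000.0
    # scanning / thresholds
    alphas: list[float] = field(default_factory=lambda: [0.05, 0.2, 0.5])
    n_perm: int = 100
    comap_lod: float = 6.1
    min_peak_separation_cM: float = 10.0
    drop_threshold: float = 2.0
    bootstrap_B: int = 200
    screen_q_cutoff: float = 0.01
    screen_abs_rho_cutoff: float = 0.35

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([cfg.seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _update_manifest(rundir: Path, stage: str, cfg: RunConfig, files: list[Path], extra: dict | None = None) -> None:
    from pleioscan import __version__

    mpath = rundir / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {"version": __version__, "stages": {}}
    manifest["stages"][stage] = {
        "seed": _stage_seed(cfg, stage),
        "files": {f.name: _sha256(f) for f in files if f.exists()},
        **(extra or {}),
    }
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, rundir: Path) -> None:
    seed = _stage_seed(cfg, "simulate")
    ss = np.random.SeedSequence(seed)
    s_map, s_gen, s_cov, s_traits, s_tax = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5))
    gmap = simulate_map(cfg.n_chromosomes, cfg.markers_per_chr, cfg.chr_length_cM, cfg.cM_per_Mbp)
    dosage = simulate_do_genomes(gmap, cfg.n_individuals, cfg.switch_density_per_cM, seed=s_gen)
    covariates = simulate_covariates(dosage.individuals, seed=s_cov)
    rng = np.random.default_rng(s_map)
    marker_ids = list(gmap.markers.index)
    specs = []
    for i in range(cfg.n_microbial):
        has_qtl = i % 2 == 0  # half the background microbes carry a QTL
        specs.append(
            TraitSpec(
                name=f"esv_{i + 1:02d}",
                trait_class="microbial",
                qtl_marker=marker_ids[rng.integers(len(marker_ids))] if has_qtl else None,
                qtl_var=cfg.qtl_var if has_qtl else 0.0,
                h2=cfg.h2,
                prevalence=cfg.prevalence,
                covariate_effects={"sex": 0.2},
            )
        )
    for i in range(cfg.n_metabolite):
        has_qtl = i % 2 == 0
        specs.append(
            TraitSpec(
                name=f"ba_{i + 1:02d}",
                trait_class="metabolite",
                qtl_marker=marker_ids[rng.integers(len(marker_ids))] if has_qtl else None,
                qtl_var=cfg.qtl_var if has_qtl else 0.0,
                h2=cfg.h2,
                covariate_effects={"sex": 0.3},
            )
        )
    pair_specs = []
    for i, p in enumerate(cfg.planted_pairs):
        p = dict(p)
        chrom = str(p.pop("chromosome", gmap.chromosomes[i % len(gmap.chromosomes)]))
        idx = gmap.chrom_slice(chrom)
        marker = p.pop("qtl_marker", marker_ids[idx[len(idx) // 2]])
        marker_b = p.pop("qtl_marker_b", None)
        pair_specs.append(
            PairSpec(
                name_a=p.pop("name_a", f"pair{i + 1}_microbe"),
                name_b=p.pop("name_b", f"pair{i + 1}_metabolite"),
                architecture=p.pop("architecture", "pleiotropic"),
                qtl_marker=marker,
                qtl_marker_b=marker_b,
                qtl_var=p.pop("qtl_var", cfg.qtl_var),
                h2=p.pop("h2", cfg.h2),
                prevalence=p.pop("prevalence", 1.0),
            )
        )
        if p:
            raise ValueError(f"unknown planted_pairs key(s): {sorted(p)}")
    counts, metabolites, clinical, truth = simulate_traits(
        dosage, gmap, covariates, specs, pair_specs, seed=s_traits
    )
    taxonomy = simulate_taxonomy(list(counts.columns), seed=s_tax)
    pio.write_map(gmap, rundir / "map.tsv")
    pio.write_dosage_hdf5(dosage, rundir / "dosage.h5")
    covariates.to_csv(rundir / "covariates.csv")
    counts.to_csv(rundir / "counts.csv")
    taxonomy.to_frame().to_csv(rundir / "taxonomy.tsv", sep="\t")
    pio.write_table(metabolites, rundir / "metabolites.csv")
    truth.to_json(rundir / "truth.json")
    _update_manifest(cfg=cfg, rundir=rundir, stage="simulate", files=[
        rundir / f for f in ["map.tsv", "dosage.h5", "covariates.csv", "counts.csv", "taxonomy.tsv", "metabolites.csv", "truth.json"]
    ])


def _load_inputs(rundir: Path):
    gmap = pio.read_map(rundir / "map.tsv")
    dosage = pio.read_dosage_hdf5(rundir / "dosage.h5")
    covariates = pd.read_csv(rundir / "covariates.csv", index_col=0)
    return gmap, dosage, covariates


def stage_preprocess(cfg: RunConfig, rundir: Path) -> None:
    counts = pio.read_table(rundir / "counts.csv")
    taxonomy = pd.read_csv(rundir / "taxonomy.tsv", sep="\t", index_col=0)["taxonomy"]
    metabolites = pio.read_table(rundir / "metabolites.csv")
    microbial = prepare_microbial(
        counts, taxonomy, cfg.min_prevalence,
        agglomerate_ranks=None, quantile_l=cfg.css_quantile, scale_constant=cfg.css_scale,
    )
    metab = prepare_metabolites(metabolites)
    from pleioscan.preprocess import TraitTable

    table = TraitTable.concat([microbial, metab])
    pio.write_trait_table(table, rundir / "traits.csv")
    _update_manifest(cfg=cfg, rundir=rundir, stage="preprocess", files=[rundir / "traits.csv", rundir / "traits.meta.json"])


def stage_scan(cfg: RunConfig, rundir: Path) -> None:
    gmap, dosage, covariates = _load_inputs(rundir)
    table = pio.read_trait_table(rundir / "traits.csv")
    kinship = compute_kinship_loco(dosage, gmap)
    scans = {}
    for name in table.values.columns:
        res = genome_scan(table.values[name], dosage, gmap, covariates, kinship, trait_name=name)
        scans[name] = res.lod
        log.info("scanned %s: max LOD %.2f", name, res.lod.max())
    pio.write_scans_long(scans, rundir / "scans.csv")
    _update_manifest(cfg=cfg, rundir=rundir, stage="scan", files=[rundir / "scans.csv"])


def stage_permute(cfg: RunConfig, rundir: Path) -> None:
    gmap, dosage, covariates = _load_inputs(rundir)
    table = pio.read_trait_table(rundir / "traits.csv")
    kinship = compute_kinship_loco(dosage, gmap)
    ts = permutation_thresholds(
        table.values, dosage, gmap, covariates, kinship,
        n_perm=cfg.n_perm, alphas=tuple(cfg.alphas), pooled=True,
        seed=_stage_seed(cfg, "permute"),
    )
    pio.write_thresholds(ts, rundir / "thresholds.json")
    _update_manifest(
        cfg=cfg, rundir=rundir, stage="permute", files=[rundir / "thresholds.json"],
        extra={"thresholds": {str(a): v for a, v in ts.thresholds.items()}},
    )


def stage_peaks(cfg: RunConfig, rundir: Path) -> None:
    gmap, dosage, covariates = _load_inputs(rundir)
    table = pio.read_trait_table(rundir / "traits.csv")
    scans = pio.read_scans_long(rundir / "scans.csv")
    kinship = compute_kinship_loco(dosage, gmap)
    from pleioscan.scan import ScanResult

    all_peaks = []
    for name, lod in scans.items():
        res = ScanResult(name, lod, {}, int(table.values[name].notna().sum()), [])
        peaks = peaks_for_trait(
            table.values[name], res, gmap, cfg.comap_lod, dosage, covariates, kinship,
            min_peak_separation_cM=cfg.min_peak_separation_cM,
            trait_class=table.trait_class.get(name, ""),
        )
        all_peaks.extend(peaks)
    pio.write_peaks(all_peaks, rundir / "peaks.csv")
    _update_manifest(
        cfg=cfg, rundir=rundir, stage="peaks", files=[rundir / "peaks.csv"],
        extra={"calling_threshold": cfg.comap_lod},
    )


def _peaks_from_csv(rundir: Path):
    from pleioscan.scan import QtlPeak

    df = pd.read_csv(rundir / "peaks.csv", dtype={"chr": str})
    peaks = []
    for _, r in df.iterrows():
        coefs = r[[f"coef_{f}" for f in "ABCDEFGH"]].to_numpy(dtype=float)
        peaks.append(
            QtlPeak(
                trait=r["trait"], chromosome=r["chr"], marker="",
                pos_Mbp=r["pos_Mbp"], pos_cM=r["pos_cM"], lod=r["lod"],
                ci_lo=r["ci_lo"], ci_hi=r["ci_hi"],
                coefs=None if np.isnan(coefs).all() else coefs,
                trait_class=r["trait_class"],
            )
        )
    return peaks


def stage_comap(cfg: RunConfig, rundir: Path) -> None:
    table = pio.read_trait_table(rundir / "traits.csv")
    peaks = _peaks_from_csv(rundir)
    microbial = [p for p in peaks if p.trait_class == "microbial"]
    metabolite = [p for p in peaks if p.trait_class == "metabolite"]
    pairs = find_overlaps(microbial, metabolite, lod_min=cfg.comap_lod)
    comap_table(pairs).to_csv(rundir / "comap_pairs.csv", index=False, float_format=pio.FLOAT_FMT)
    screen = spearman_bh_screen(
        table.subset("microbial"), table.subset("metabolite"),
        q_cutoff=cfg.screen_q_cutoff, abs_rho_cutoff=cfg.screen_abs_rho_cutoff,
    )
    screen.table.to_csv(rundir / "screen.csv", index=False, float_format=pio.FLOAT_FMT)
    _update_manifest(
        cfg=cfg, rundir=rundir, stage="comap",
        files=[rundir / "comap_pairs.csv", rundir / "screen.csv"],
        extra={"comap_lod": cfg.comap_lod},
    )


def _interval_markers(
    gmap, chrom: str, lo_mbp: float, hi_mbp: float, pad_cM: float = 2.0, min_markers: int = 5
) -> np.ndarray:
    """Markers spanning [lo, hi] Mbp padded by ``pad_cM``, grown symmetrically
    to at least ``min_markers`` so the profile grid is never degenerate."""
    idx = gmap.chrom_slice(chrom)
    cm = gmap.markers["pos_cM"].to_numpy()[idx]
    mbp = gmap.markers["pos_Mbp"].to_numpy()[idx]
    inside = (mbp >= lo_mbp) & (mbp <= hi_mbp)
    if not inside.any():
        inside = np.zeros_like(inside)
        inside[np.argmin(np.abs(mbp - (lo_mbp + hi_mbp) / 2))] = True
    lo_cm, hi_cm = cm[inside].min() - pad_cM, cm[inside].max() + pad_cM
    sel = np.flatnonzero((cm >= lo_cm) & (cm <= hi_cm))
    lo, hi = int(sel.min()), int(sel.max())
    while hi - lo + 1 < min(min_markers, len(idx)):
        lo = max(lo - 1, 0)
        hi = min(hi + 1, len(idx) - 1)
    return idx[lo : hi + 1]


def stage_pleio(cfg: RunConfig, rundir: Path) -> None:
    gmap, dosage, covariates = _load_inputs(rundir)
    table = pio.read_trait_table(rundir / "traits.csv")
    comap = pd.read_csv(rundir / "comap_pairs.csv", dtype={"chr": str})
    peaks_df = pd.read_csv(rundir / "peaks.csv", dtype={"chr": str})
    seed = _stage_seed(cfg, "pleio")
    results = []
    for k, row in comap.iterrows():
        # grid over the union of the two traits' support intervals (padded)
        sel = peaks_df[
            (peaks_df["chr"] == row["chr"])
            & peaks_df["trait"].isin([row["trait_a"], row["trait_b"]])
        ]
        idx = _interval_markers(gmap, row["chr"], sel["ci_lo"].min(), sel["ci_hi"].max())
        if len(idx) < 2:
            continue
        res = bootstrap_pvalue(
            table.values[row["trait_a"]].to_numpy(dtype=float),
            table.values[row["trait_b"]].to_numpy(dtype=float),
            dosage.dosage[:, idx, :],
            covariates,
            B=cfg.bootstrap_B,
            seed=(seed + int(k)) % 2**31,
            markers=[str(m) for m in gmap.markers.index[idx]],
        )
        results.append(
            {
                "trait_a": row["trait_a"],
                "trait_b": row["trait_b"],
                "chr": row["chr"],
                "interval": [res.markers[0], res.markers[-1]],
                "lrt": res.lrt,
                "B": res.B,
                "p": res.pvalue,
                "argmax": list(res.argmax),
                "n_nonconverged": res.n_nonconverged,
            }
        )
    (rundir / "pleio_results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    _update_manifest(cfg=cfg, rundir=rundir, stage="pleio", files=[rundir / "pleio_results.json"], extra={"B": cfg.bootstrap_B})


def stage_mediate(cfg: RunConfig, rundir: Path) -> None:
    gmap, dosage, covariates = _load_inputs(rundir)
    table = pio.read_trait_table(rundir / "traits.csv")
    comap = pd.read_csv(rundir / "comap_pairs.csv", dtype={"chr": str})
    kinship = compute_kinship_loco(dosage, gmap)
    scans = pio.read_scans_long(rundir / "scans.csv")
    med_rows, verdict_rows = [], []
    for _, row in comap.iterrows():
        idx = gmap.chrom_slice(row["chr"])
        la = scans[row["trait_a"]].iloc[idx]
        lb = scans[row["trait_b"]].iloc[idx]
        locus = (la + lb).idxmax()
        rep = bidirectional_report(
            table.values[row["trait_a"]], table.values[row["trait_b"]],
            dosage, gmap, covariates, kinship, locus,
            name_a=row["trait_a"], name_b=row["trait_b"],
        )
        for r in (rep.a_given_b, rep.b_given_a):
            med_rows.append(
                {
                    "target": r.target, "mediator": r.mediator, "chr": r.chromosome,
                    "pos": locus, "lod_orig": r.lod_original, "lod_cond": r.lod_conditioned,
                    "drop": r.lod_drop, "pass": r.lod_drop > cfg.drop_threshold,
                }
            )
        verdict_rows.append(
            {
                "pair": f"{row['trait_a']}|{row['trait_b']}",
                **{f"bic_{k}": v for k, v in rep.verdict.scores.items()},
                "label": rep.verdict.label,
                "margin": rep.verdict.margin,
            }
        )
    med_cols = ["target", "mediator", "chr", "pos", "lod_orig", "lod_cond", "drop", "pass"]
    verdict_cols = ["pair", "bic_m1", "bic_m2", "bic_m3", "bic_m4", "label", "margin"]
    pd.DataFrame(med_rows, columns=med_cols).to_csv(rundir / "mediation.csv", index=False, float_format=pio.FLOAT_FMT)
    pd.DataFrame(verdict_rows, columns=verdict_cols).to_csv(rundir / "verdicts.csv", index=False, float_format=pio.FLOAT_FMT)
    _update_manifest(
        cfg=cfg, rundir=rundir, stage="mediate",
        files=[rundir / "mediation.csv", rundir / "verdicts.csv"],
        extra={"drop_threshold": cfg.drop_threshold},
    )


def stage_report(cfg: RunConfig, rundir: Path) -> None:
    lines = ["pleioscan run report", "=" * 40]
    peaks_path = rundir / "peaks.csv"
    if peaks_path.exists():
        peaks = pd.read_csv(peaks_path)
        lines.append(f"QTL peaks called (LOD >= {cfg.comap_lod}): {len(peaks)}")
        if len(peaks) == 0:
            lines.append("  zero peaks above the calling threshold")
        else:
            for _, r in peaks.iterrows():
                lines.append(
                    f"  {r['trait']} [{r['trait_class']}] chr{r['chr']} @ {r['pos_Mbp']:.1f} Mbp "
                    f"LOD {r['lod']:.2f} CI [{r['ci_lo']:.1f}, {r['ci_hi']:.1f}]"
                )
    else:
        lines.append("peaks: not run")
    th_path = rundir / "thresholds.json"
    if th_path.exists():
        ts = pio.read_thresholds(th_path)
        lines.append("Permutation thresholds (pooled):")
        for a in sorted(ts.thresholds):
            lines.append(f"  alpha {a}: LOD >= {ts.thresholds[a]:.2f}")
    else:
        lines.append("thresholds: not run")
    comap_path = rundir / "comap_pairs.csv"
    if comap_path.exists():
        comap = pd.read_csv(comap_path)
        lines.append(f"Co-mapping microbe-metabolite pairs: {len(comap)}")
        for _, r in comap.iterrows():
            lines.append(
                f"  {r['trait_a']} x {r['trait_b']} chr{r['chr']} "
                f"overlap [{r['overlap_lo']:.1f}, {r['overlap_hi']:.1f}] Mbp r_effects {r['r_effects']:.2f}"
            )
    else:
        lines.append("comap: not run")
    pleio_path = rundir / "pleio_results.json"
    if pleio_path.exists():
        res = json.loads(pleio_path.read_text())
        lines.append("Pleiotropy tests:")
        for r in res:
            lines.append(f"  {r['trait_a']} x {r['trait_b']}: lrt {r['lrt']:.3f}, bootstrap p {r['p']:.3f} (B={r['B']})")
    else:
        lines.append("pleiotropy: not run")
    med_path = rundir / "mediation.csv"
    if med_path.exists():
        med = pd.read_csv(med_path)
        lines.append("Mediation (LOD drops):")
        for _, r in med.iterrows():
            lines.append(
                f"  {r['target']} | {r['mediator']}: {r['lod_orig']:.2f} -> {r['lod_cond']:.2f} "
                f"(drop {r['drop']:.2f}{', passes' if r['pass'] else ''})"
            )
        verd = pd.read_csv(rundir / "verdicts.csv")
        lines.append("Causal model selection:")
        for _, r in verd.iterrows():
            lines.append(f"  {r['pair']}: {r['label']} (margin {r['margin']:.2f})")
    else:
        lines.append("mediation: not run")
    (rundir / "report.txt").write_text("\n".join(lines) + "\n")
    _update_manifest(cfg=cfg, rundir=rundir, stage="report", files=[rundir / "report.txt"])


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "scan": stage_scan,
    "permute": stage_permute,
    "peaks": stage_peaks,
    "comap": stage_comap,
    "pleio": stage_pleio,
    "mediate": stage_mediate,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order; a stage failure halts the run
    with the stage named, keeping partial outputs in the run directory."""
    rundir = Path(out_dir if out_dir is not None else cfg.out_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(rundir / "config.yaml")
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("stage %s", stage)
        try:
            STAGE_FUNCS[stage](cfg, rundir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return rundir
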