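"""Configuration-driven orchestration: simulate -> efd -> pca -> popgen ->
stats -> divergence, with every intermediate materialized as CSV/FASTA/JSON.

Each stage reads the previous stage's files and writes its own, so any stage
can be rerun or audited in isolation; reruns with the same config and seed
are bit-identical.  A machine-readable run report collects record counts,
seeds and warnings per stage.

File dialects
-------------
* contour CSV: one row per outline point with columns specimen_id, fish_id,
  species, site, sex, side, area_um2, point_index, x, y (points ordered,
  closed implicitly);
* TPS outline files: OUTLINES/POINTS headers, whitespace-separated x y
  rows, ID=<specimen> record terminator;
* FASTA: one file per population (Biopython), plus an optional
  population-map TSV (sequence_id <tab> population) for pooled files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import divergence as dv
from . import efd as efd_mod
from . import popgen as pg
from . import shapepca as sp
from . import shapestats as st
from . import synthdata as sd
from .efd import Contour

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_contour_csv",
    "write_contour_csv",
    "read_tps",
    "write_tps",
    "read_fasta_populations",
    "write_fasta_populations",
]

_FLOAT_FMT = "%.17g"  # exact float round-trip
_STAGES = ("simulate", "efd", "pca", "popgen", "stats", "divergence")


@dataclass
class PipelineConfig:
    """Settings for a full run; defaults mirror the analysis conventions
    (99.999% cumulative-power harmonic selection, 1,023 permutations,
    Bonferroni family of 24 sex tests implied by the 2 x 4 x 3 grid)."""

    out_dir: str = "otomorph_out"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    # inputs when not simulating
    contours_csv: str | None = None
    fasta_dir: str | None = None
    # simulation settings
    study: sd.StudyDesignConfig = field(default_factory=sd.StudyDesignConfig)
    haplotypes: sd.HaplotypeSimConfig = field(default_factory=sd.HaplotypeSimConfig)
    species_admixture: dict = field(
        default_factory=lambda: {
            "caudopunctatus": 0.25, "pulcher": 0.5, "savoryi": 0.9, "moorii": 0.35
        }
    )
    # analysis settings
    harmonic_threshold: float = 0.99999
    max_harmonics: int = 25
    resample_points: int = 512
    n_permutations: int = 1023
    exclude_divergent_haplotypes: bool = True
    pcs: tuple[str, ...] = ("PC1", "PC2")

    def __post_init__(self) -> None:
        if not (0.0 < self.harmonic_threshold <= 1.0):
            raise ValueError("harmonic_threshold must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study = sd.StudyDesignConfig(**raw.pop("study", {}))
        haps = sd.HaplotypeSimConfig(**raw.pop("haplotypes", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "pcs" in raw:
            raw["pcs"] = tuple(raw["pcs"])
        return cls(study=study, haplotypes=haps, **raw)


# ---------------------------------------------------------------------------
# I/O: contour CSV, TPS, FASTA
# ---------------------------------------------------------------------------

_META_COLS = ("fish_id", "species", "site", "sex", "side", "area_um2")


def write_contour_csv(contours: list[Contour], path: str | Path) -> None:
    frames = []
    for c in contours:
        k = c.n_points
        frame = {
            "specimen_id": np.repeat(c.specimen_id, k),
            "point_index": np.arange(k),
            "x": c.points[:, 0],
            "y": c.points[:, 1],
        }
        for col in _META_COLS:
            frame[col] = np.repeat(c.metadata.get(col, "" if col != "area_um2" else np.nan), k)
        frames.append(pd.DataFrame(frame))
    cols = ["specimen_id", *_META_COLS, "point_index", "x", "y"]
    pd.concat(frames)[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_contour_csv(path: str | Path) -> list[Contour]:
    """Parse the contour dialect; malformed groups are reported with the
    first offending line number."""
    df = pd.read_csv(path)
    required = {"specimen_id", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    unknown = set(df.columns) - required - set(_META_COLS)
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {sorted(unknown)}")
    contours = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        if not np.array_equal(grp["point_index"].to_numpy(), np.arange(len(grp))):
            line = int(grp.index[0]) + 2  # header + 0-based
            raise ValueError(
                f"{path}: specimen {sid!r} has non-contiguous point_index "
                f"(starting near line {line})"
            )
        meta = {c: grp[c].iloc[0] for c in _META_COLS if c in grp}
        side = str(meta.get("side", "left")) or "left"
        try:
            contours.append(
                Contour(
                    points=grp[["x", "y"]].to_numpy(float),
                    specimen_id=str(sid),
                    side=side,
                    metadata=meta,
                )
            )
        except ValueError as exc:
            line = int(grp.index[0]) + 2
            raise ValueError(f"{path}: specimen {sid!r} (line {line}): {exc}") from exc
    return contours


def write_tps(contours: list[Contour], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contours:
            fh.write("LM=0\nOUTLINES=1\n")
            fh.write(f"POINTS={c.n_points}\n")
            for x, y in c.points:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={c.specimen_id}\n")


def read_tps(path: str | Path) -> list[Contour]:
    """Read TPS outline records (LM/OUTLINES/POINTS headers, ID terminator)."""
    contours: list[Contour] = []
    points: list[tuple[float, float]] = []
    expected = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith(("LM=", "OUTLINES=", "IMAGE=", "SCALE=", "CURVES=")):
                continue
            if upper.startswith("POINTS="):
                expected = int(line.split("=", 1)[1])
                continue
            if upper.startswith("ID="):
                sid = line.split("=", 1)[1]
                if expected is not None and len(points) != expected:
                    raise ValueError(
                        f"{path}:{lineno}: specimen {sid!r} declares "
                        f"{expected} points but has {len(points)}"
                    )
                contours.append(Contour(points=np.array(points), specimen_id=sid))
                points, expected = [], None
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'x y', got {line!r}")
            points.append((float(parts[0]), float(parts[1])))
    if points:
        raise ValueError(f"{path}: trailing points without an ID= terminator")
    return contours


def write_fasta_populations(
    alignments: dict[str, pg.HaplotypeAlignment], out_dir: str | Path
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pop, aln in alignments.items():
        records = [
            SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(aln.ids, aln.sequences)
        ]
        p = out_dir / f"{pop}.fasta"
        SeqIO.write(records, p, "fasta")
        paths.append(p)
    return paths


def read_fasta_populations(
    fasta_dir: str | Path | None = None,
    fasta: str | Path | None = None,
    popmap: str | Path | None = None,
) -> dict[str, pg.HaplotypeAlignment]:
    """One FASTA per population (directory mode) or one pooled FASTA with a
    two-column population-map TSV."""
    out: dict[str, pg.HaplotypeAlignment] = {}
    if fasta_dir is not None:
        for p in sorted(Path(fasta_dir).glob("*.fasta")):
            recs = list(SeqIO.parse(str(p), "fasta"))
            if not recs:
                raise ValueError(f"{p}: empty FASTA")
            L = len(recs[0].seq)
            for r in recs:
                if len(r.seq) != L:
                    raise ValueError(
                        f"{p}: sequence {r.id!r} has length {len(r.seq)}, "
                        f"expected {L} (alignment must be equal-length)"
                    )
            out[p.stem] = pg.HaplotypeAlignment(
                population=p.stem,
                ids=[r.id for r in recs],
                sequences=[str(r.seq) for r in recs],
            )
    elif fasta is not None and popmap is not None:
        mapping = {}
        with open(popmap) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{popmap}:{lineno}: expected 'id<TAB>population'")
                mapping[parts[0]] = parts[1]
        groups: dict[str, tuple[list, list]] = {}
        for r in SeqIO.parse(str(fasta), "fasta"):
            if r.id not in mapping:
                raise ValueError(f"{fasta}: sequence {r.id!r} missing from popmap")
            ids, seqs = groups.setdefault(mapping[r.id], ([], []))
            ids.append(r.id)
            seqs.append(str(r.seq))
        out = {
            pop: pg.HaplotypeAlignment(population=pop, ids=i, sequences=s)
            for pop, (i, s) in groups.items()
        }
    else:
        raise ValueError("give fasta_dir, or fasta together with popmap")
    if not out:
        raise ValueError("no populations found")
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path, report: dict) -> None:
    study = replace(cfg.study, seed=cfg.seed)
    contours, metadata, truth = sd.generate_otolith_dataset(study)
    write_contour_csv(contours, out / "contours.csv")
    metadata.to_csv(out / "metadata.csv", index=False, float_format=_FLOAT_FMT)
    truth["otolith_truth"].to_csv(
        out / "ground_truth.csv", index=False, float_format=_FLOAT_FMT
    )
    (out / "ground_truth_config.json").write_text(
        json.dumps(truth["config"], indent=2, sort_keys=True)
    )
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(1,))
    hap_counts = {}
    for child, species in zip(ss.spawn(len(study.species)), study.species):
        m = cfg.species_admixture.get(species, cfg.haplotypes.m)
        hcfg = replace(
            cfg.haplotypes,
            populations=tuple(study.sites),
            m=m,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        pops = sd.simulate_haplotype_populations(hcfg)
        write_fasta_populations(pops, out / "haplotypes" / species)
        hap_counts[species] = {p: len(a) for p, a in pops.items()}
    report["simulate"] = {
        "n_contours": len(contours),
        "n_fish": int(metadata["fish_id"].nunique()),
        "haplotype_samples": hap_counts,
    }


def _stage_efd(cfg: PipelineConfig, out: Path, report: dict) -> None:
    src = cfg.contours_csv or out / "contours.csv"
    contours = read_contour_csv(src)
    n_mirrored = 0
    normalized: dict[str, list] = {}
    for c in contours:
        if c.side == "right":
            c = efd_mod.mirror_contour(c)
            n_mirrored += 1
        c = efd_mod.resample_contour(c, cfg.resample_points)
        e = efd_mod.normalize_efd(efd_mod.compute_efd(c, cfg.max_harmonics))
        normalized.setdefault(str(c.metadata.get("species", "all")), []).append(e)

    chosen: dict[str, int] = {}
    coeff_rows = []
    spectra_rows = []
    for species, efds in sorted(normalized.items()):
        mat = sp.coefficient_matrix(efds)
        mean_coeffs = efd_mod.EFDCoefficients(
            coeffs=mat.to_numpy().mean(axis=0).reshape(-1, 4), normalized=False
        )
        spec = efd_mod.power_spectrum(mean_coeffs)
        n_sel = efd_mod.select_harmonics(spec, cfg.harmonic_threshold)
        chosen[species] = n_sel
        for n, (p, f) in enumerate(zip(spec.power, spec.cumulative), start=1):
            spectra_rows.append(
                {"species": species, "harmonic": n, "power": p, "cumulative": f}
            )
        for e in efds:
            for n in range(n_sel):
                a, b, c_, d = e.coeffs[n]
                coeff_rows.append(
                    {"specimen_id": e.specimen_id, "species": species,
                     "harmonic": n + 1, "a": a, "b": b, "c": c_, "d": d}
                )
    pd.DataFrame(coeff_rows).to_csv(
        out / "efd_coefficients.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(spectra_rows).to_csv(
        out / "power_spectra.csv", index=False, float_format=_FLOAT_FMT
    )
    (out / "harmonic_counts.json").write_text(json.dumps(chosen, indent=2, sort_keys=True))
    report["efd"] = {
        "n_contours": len(contours),
        "n_mirrored": n_mirrored,
        "harmonics_per_species": chosen,
    }


def _efds_from_table(df: pd.DataFrame) -> dict[str, list[efd_mod.EFDCoefficients]]:
    by_species: dict[str, list] = {}
    for (species, sid), grp in df.groupby(["species", "specimen_id"], sort=True):
        grp = grp.sort_values("harmonic")
        e = efd_mod.EFDCoefficients(
            coeffs=grp[["a", "b", "c", "d"]].to_numpy(float),
            normalized=True,
            specimen_id=str(sid),
        )
        by_species.setdefault(str(species), []).append(e)
    return by_species


def _stage_pca(cfg: PipelineConfig, out: Path, report: dict) -> None:
    src = out / "efd_coefficients.csv"
    if not src.exists():
        raise FileNotFoundError("pca stage requires efd stage outputs (efd_coefficients.csv)")
    table = pd.read_csv(src)
    info = {}
    all_scores = []
    recon_rows = []
    for species, efds in sorted(_efds_from_table(table).items()):
        pca = sp.fit_shape_pca(sp.coefficient_matrix(efds))
        n_keep = sp.select_pcs(pca)
        info[species] = {
            "n_components": pca.n_components,
            "retained": n_keep,
            "proportions": pca.proportions[: max(n_keep, 2)].round(6).tolist(),
        }
        scores = pca.scores.copy()
        scores.insert(0, "species", species)
        all_scores.append(scores.reset_index())
        for pc in range(1, max(n_keep, 2) + 1):
            for sd_mult in (-2.0, 0.0, 2.0):
                c = sp.pc_extreme_contour(pca, pc, sd_mult, K=128)
                for i, (x, y) in enumerate(c.points):
                    recon_rows.append(
                        {"species": species, "pc": pc, "sd_multiple": sd_mult,
                         "point_index": i, "x": x, "y": y}
                    )
    scores_df = pd.concat(all_scores, ignore_index=True)
    scores_df.to_csv(out / "pc_scores.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(recon_rows).to_csv(
        out / "pc_reconstructions.csv", index=False, float_format=_FLOAT_FMT
    )
    (out / "pca_report.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    report["pca"] = info


def _stage_popgen(cfg: PipelineConfig, out: Path, report: dict) -> None:
    hap_root = Path(cfg.fasta_dir) if cfg.fasta_dir else out / "haplotypes"
    if not hap_root.exists():
        raise FileNotFoundError(f"popgen stage requires haplotype FASTAs under {hap_root}")
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(3,))
    tables = []
    species_dirs = sorted(p for p in hap_root.iterdir() if p.is_dir())
    if not species_dirs:
        species_dirs = [hap_root]
    for child, sp_dir in zip(ss.spawn(len(species_dirs)), species_dirs):
        alignments = read_fasta_populations(fasta_dir=sp_dir)
        tab = pg.pairwise_phi_st_table(
            alignments,
            n_perm=cfg.n_permutations,
            seed=int(child.generate_state(1)[0] % (2**31)),
            exclude_divergent=cfg.exclude_divergent_haplotypes,
        )
        tab.insert(0, "species", sp_dir.name if sp_dir != hap_root else "all")
        tables.append(tab)
    phi = pd.concat(tables, ignore_index=True)
    phi.to_csv(out / "phi_st.csv", index=False, float_format=_FLOAT_FMT)
    report["popgen"] = {
        "n_pairs": len(phi),
        "n_permutations": cfg.n_permutations,
        "phi_st_range": [float(phi["phi_st"].min()), float(phi["phi_st"].max())],
    }


def _load_stats_dataset(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    scores_path = out / "pc_scores.csv"
    meta_path = Path(cfg.contours_csv).parent / "metadata.csv" if cfg.contours_csv else out / "metadata.csv"
    if not scores_path.exists():
        raise FileNotFoundError("stats stage requires pca stage outputs (pc_scores.csv)")
    if not meta_path.exists():
        raise FileNotFoundError(f"stats stage requires specimen metadata ({meta_path})")
    scores = pd.read_csv(scores_path).set_index("specimen_id").drop(columns=["species"])
    metadata = pd.read_csv(meta_path)
    return st.assemble_records(scores, metadata)


def _stage_stats(cfg: PipelineConfig, out: Path, report: dict) -> None:
    dataset = _load_stats_dataset(cfg, out)
    dataset.to_csv(out / "otolith_records.csv", index=False, float_format=_FLOAT_FMT)
    tests, alpha = st.sex_difference_tests(dataset, pcs=cfg.pcs)
    tests.to_csv(out / "sex_tests.csv", index=False, float_format=_FLOAT_FMT)
    contrasts = pd.concat(
        [st.site_contrasts(dataset, sex, pcs=cfg.pcs) for sex in ("F", "M")],
        ignore_index=True,
    )
    contrasts.to_csv(out / "site_contrasts.csv", index=False, float_format=_FLOAT_FMT)
    report["stats"] = {
        "n_sex_tests": len(tests),
        "bonferroni_alpha": alpha,
        "n_significant_sex_tests": int(tests["significant"].sum()),
        "n_site_contrasts": len(contrasts),
    }


def _stage_divergence(cfg: PipelineConfig, out: Path, report: dict) -> None:
    phi_path = out / "phi_st.csv"
    if not phi_path.exists():
        raise FileNotFoundError(
            "divergence stage requires popgen stage outputs (phi_st.csv); "
            "enable the popgen stage or provide the file"
        )
    dataset = _load_stats_dataset(cfg, out)
    diffs = dv.extract_difference_measures(dataset, pcs=cfg.pcs)
    diffs.to_csv(out / "difference_measures.csv", index=False, float_format=_FLOAT_FMT)
    phi = pd.read_csv(phi_path)
    fit = dv.fit_divergence_model(diffs, phi)
    fit.table.to_csv(out / "divergence_effects.csv", index=False, float_format=_FLOAT_FMT)
    n_model_pairs = diffs.groupby(["sex", "species", "pc"]).ngroups
    report["divergence"] = {
        "n_difference_rows": len(diffs),
        "n_model_pairs": n_model_pairs,
        "n_measures": int(diffs["measure"].nunique()),
        "n_cis": len(fit.table),
        "n_cis_excluding_zero": int(fit.table["excludes_zero"].sum()),
        "variance_components": {k: float(v) for k, v in fit.vcomp.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    A stage failure aborts downstream stages but preserves completed
    outputs; the report is written to <out_dir>/run_report.json either way.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    report: dict = {
        "otomorph_version": __version__,
        "seed": config.seed,
        "stages_requested": list(config.stages),
        "stages_completed": [],
    }
    stage_fns = {
        "simulate": _stage_simulate,
        "efd": _stage_efd,
        "pca": _stage_pca,
        "popgen": _stage_popgen,
        "stats": _stage_stats,
        "divergence": _stage_divergence,
    }
    try:
        for stage in _STAGES:
            if stage not in config.stages:
                continue
            logger.info("running stage: %s", stage)
            stage_fns[stage](config, out, report)
            report["stages_completed"].append(stage)
    except Exception as exc:
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
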