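"""TSV schemas, run configuration, and the end-to-end pipeline.

All interchange is plain TSV with documented headers and BED-convention
coordinates (0-based, half-open). Readers validate against a declared
schema and fail with the offending column or row named; write-then-read
round-trips reproduce records exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cftriage.classify import compare_feature_sets
from cftriage.concordance import partition_mutations, tmb_concordance
from cftriage.errors import ConfigurationError, SchemaError
from cftriage.fragments import DEFAULT_WINDOWS, FragmentLengthHistogram, FragmentSizeFeaturizer
from cftriage.genome import GenomeDef
from cftriage.mutations import (
    MVAF_HIGH_CUT,
    TMB_PANEL_BP,
    AssayLimits,
    SampleMutationProfile,
    call_mutations,
    tmb as tmb_fn,
)
from cftriage.simulate import SimulationConfig, simulate_cohort
from cftriage.swgs import Z_HIGH_CUT, GenomeWideZScorer
from cftriage.triage import decisions_frame, summarize_cohort, triage_sample

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableSchema:
    """Declared column contract for one TSV interchange format."""

    name: str
    columns: tuple[tuple[str, type], ...]  # required columns, in order
    optional: tuple[tuple[str, type], ...] = ()

    def required_names(self) -> list[str]:
        return [c for c, _ in self.columns]


BINS_SCHEMA = TableSchema(
    "bin_counts",
    (("chrom", str), ("start", int), ("end", int), ("gc", float), ("count", int)),
    optional=(("bin_id", str), ("segment_id", str)),
)
LENGTHS_SCHEMA = TableSchema("fragment_lengths", (("length", int), ("count", int)))
MAF_SCHEMA = TableSchema(
    "mutation_calls",
    (
        ("sample", str),
        ("locus", str),
        ("chrom", str),
        ("pos", int),
        ("ref", str),
        ("alt", str),
        ("alt_count", int),
        ("depth", int),
    ),
    optional=(
        ("ccf", float),
        ("hotspot", bool),
        ("in_panel", bool),
        ("in_targeted", bool),
        ("known_in_tumor", bool),
        ("assay", str),
        ("synonymous", bool),
        ("oncokb_level", str),
        ("msi_score", float),
    ),
)
TF_SCHEMA = TableSchema(
    "tumor_fraction",
    (("sample", str), ("S", float), ("Z", float), ("tf_class", str)),
    optional=(("tf_band", str),),
)
META_SCHEMA = TableSchema(
    "sample_meta",
    (("sample", str),),
    optional=(("tf_class", str), ("Z", float), ("interval_days", int)),
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a TSV against its schema.

    Missing required columns, unparseable numbers and bad coordinates are
    reported with the column name and 1-based data row number.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in schema.required_names() if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing required column(s) {missing} in {path}")
    for col, typ in schema.columns + schema.optional:
        if col not in df.columns:
            continue
        try:
            if typ is bool:
                df[col] = df[col].str.lower().map({"true": True, "false": False, "1": True, "0": False})
                if df[col].isna().any():
                    row = int(df[col].isna().idxmax()) + 1
                    raise ValueError(f"row {row}")
            elif typ in (int, float):
                df[col] = pd.to_numeric(df[col], errors="raise").astype(typ)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{schema.name}: column {col!r} is not {typ.__name__} ({exc})") from exc
    if {"start", "end"} <= set(df.columns):
        bad = df["start"] >= df["end"]
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(f"{schema.name}: start >= end at data row {row} (0-based half-open expected)")
    return df


def write_table(df: pd.DataFrame, path, schema: TableSchema | None = None) -> None:
    if schema is not None:
        missing = [c for c in schema.required_names() if c not in df.columns]
        if missing:
            raise SchemaError(f"{schema.name}: refusing to write without column(s) {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_bin_counts(sample, genome: GenomeDef, path) -> None:
    df = genome.bins.copy()
    df["count"] = sample.bin_counts
    write_table(df[["chrom", "start", "end", "gc", "count", "bin_id", "segment_id"]], path)


def read_bin_counts(path) -> np.ndarray:
    return read_table(path, BINS_SCHEMA)["count"].to_numpy(np.int64)


def write_lengths(sample, path) -> None:
    counts = sample.fragment_length_counts
    nz = np.nonzero(counts)[0]
    write_table(pd.DataFrame({"length": nz, "count": counts[nz]}), path, LENGTHS_SCHEMA)


def read_histogram(path, sample_id: str) -> FragmentLengthHistogram:
    return FragmentLengthHistogram.from_counts(sample_id, read_table(path, LENGTHS_SCHEMA))


@dataclass
class Thresholds:
    """All decision constants of the workflow, overridable from config."""

    z_cut: float = Z_HIGH_CUT
    mvaf_cut: float = MVAF_HIGH_CUT
    ccf_cut: float = 0.75
    tmb_cut: float = 10.0
    panel_bp: int = TMB_PANEL_BP
    vaf_genotyping: float = 0.01
    vaf_hotspot: float = 0.02
    vaf_nonhotspot: float = 0.05
    vaf_ultradeep: float = 0.001

    def limits(self, mode: str) -> AssayLimits:
        return AssayLimits(
            mode=mode,
            vaf_genotyping=self.vaf_genotyping,
            vaf_hotspot=self.vaf_hotspot,
            vaf_nonhotspot=self.vaf_nonhotspot,
            vaf_ultradeep=self.vaf_ultradeep,
        )


@dataclass
class RunConfig:
    """Seed, thresholds and simulation parameters for a pipeline run."""

    seed: int = 0
    out_dir: str = "cftriage_run"
    thresholds: Thresholds = field(default_factory=Thresholds)
    windows: tuple = DEFAULT_WINDOWS
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
        raw = raw or {}
        thr_over = raw.pop("thresholds", {})
        thr = Thresholds()
        for k, v in thr_over.items():
            if not hasattr(thr, k):
                raise ConfigurationError(f"unknown threshold {k!r}")
            log.info("threshold override: %s = %s (default %s)", k, v, getattr(thr, k))
            setattr(thr, k, v)
        sim_over = raw.pop("sim", {})
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_over) - sim_fields
        if unknown:
            raise ConfigurationError(f"unknown sim parameter(s) {sorted(unknown)}")
        seed = raw.pop("seed", 0)
        sim_over.setdefault("seed", seed)
        windows = tuple(tuple(w) for w in raw.pop("windows", DEFAULT_WINDOWS))
        out_dir = raw.pop("out_dir", "cftriage_run")
        if raw:
            raise ConfigurationError(f"unknown config key(s) {sorted(raw)}")
        return cls(seed=seed, out_dir=out_dir, thresholds=thr, windows=windows, sim=SimulationConfig(**sim_over))


def _sha1(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute simulate -> tf -> fragsize -> callmuts -> concordance -> triage -> report.

    Writes every stage artifact under ``out_dir`` and returns the cohort
    summary dict. All randomness flows from ``cfg.seed``; a manifest
    records the seed, thresholds and output hashes so a rerun can be
    verified bit-identical.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    genome = GenomeDef.toy()
    genome.to_tsv(out / "genome.tsv")

    cohort = simulate_cohort(cfg.sim, genome)
    log.info("simulate: %d healthy, %d patients", len(cohort.healthy), len(cohort.patients))
    write_table(cohort.truth, out / "truth.tsv")

    # --- tumor fraction ------------------------------------------------
    scorer = GenomeWideZScorer(genome, z_threshold=thr.z_cut)
    scorer.fit(np.stack([h.bin_counts for h in cohort.healthy]))
    pat_counts = np.stack([p.bin_counts for p in cohort.patients])
    pat_ids = [p.sample_id for p in cohort.patients]
    tf = scorer.score_table(pat_counts, pat_ids)
    write_table(tf, out / "tf.tsv", TF_SCHEMA)

    # --- fragment sizes ------------------------------------------------
    feat = FragmentSizeFeaturizer(windows=cfg.windows)
    hists = [
        FragmentLengthHistogram(s.sample_id, s.fragment_length_counts)
        for s in cohort.all_samples
    ]
    sizes = feat.transform(hists)
    write_table(sizes.reset_index(), out / "sizes.tsv")

    # --- stage-1 mutation calling (targeted; genotyping when tumor known)
    gz_by_id = {sid: scorer.score_sample(c, sid) for sid, c in zip(pat_ids, pat_counts)}
    stage1: dict[str, SampleMutationProfile] = {}
    tumor_rows, plasma_rows = [], []
    for p in cohort.patients:
        muts = p.mutations.copy()
        tumor_available = bool(p.truth.get("tumor_available", False))
        calls = muts.rename(columns={"alt_targeted": "alt_count", "depth_targeted": "depth"})
        if tumor_available:
            tcalls = muts.rename(columns={"alt_tumor": "alt_count", "depth_tumor": "depth"})
            tdet = call_mutations(tcalls, thr.limits("de_novo"))
            known = set(tdet.loc[tdet["detected"], "locus"])
            calls["known_in_tumor"] = calls["locus"].isin(known)
            for _, r in tdet.loc[tdet["detected"]].iterrows():
                tumor_rows.append({"sample": p.sample_id, **{k: r[k] for k in ("locus", "chrom", "pos", "ref", "alt", "ccf")}})
            mode = "genotyping"
        else:
            calls["known_in_tumor"] = False
            mode = "de_novo"
        prof = SampleMutationProfile.from_calls(p.sample_id, calls, thr.limits(mode), thr.panel_bp)
        stage1[p.sample_id] = prof
        det = prof.calls.loc[prof.calls["detected"]]
        for _, r in det.iterrows():
            plasma_rows.append({"sample": p.sample_id, **{k: r[k] for k in ("locus", "chrom", "pos", "ref", "alt", "ccf")}})
    write_table(pd.DataFrame([pr.as_row() for pr in stage1.values()]), out / "profiles_stage1.tsv")

    # --- concordance (tumor-available subset) --------------------------
    tumor_df = pd.DataFrame(tumor_rows)
    plasma_df = pd.DataFrame(plasma_rows)
    if len(tumor_df) and len(plasma_df):
        conc = partition_mutations(tumor_df, plasma_df)
        write_table(conc, out / "concordance.tsv")
    else:
        conc = None

    # --- triage + stage 2 ----------------------------------------------
    decisions = [triage_sample(stage1[sid], gz_by_id[sid], z_threshold=thr.z_cut) for sid in pat_ids]
    write_table(decisions_frame(decisions), out / "decisions.tsv")
    stage2: dict[str, SampleMutationProfile] = {}
    for d in decisions:
        p = next(s for s in cohort.patients if s.sample_id == d.sample_id)
        if d.decision == "reflex_ultradeep":
            calls = p.mutations.rename(columns={"alt_ultradeep": "alt_count", "depth_ultradeep": "depth"})
            stage2[d.sample_id] = SampleMutationProfile.from_calls(
                d.sample_id, calls, thr.limits("ultradeep"), thr.panel_bp
            )
        elif d.decision == "reflex_exome":
            # exome-scale profiling sees every locus at ~5% sensitivity
            calls = p.mutations.rename(columns={"alt_targeted": "alt_count", "depth_targeted": "depth"})
            calls = calls.drop(columns=["in_targeted"])
            stage2[d.sample_id] = SampleMutationProfile.from_calls(
                d.sample_id, calls, thr.limits("de_novo"), thr.panel_bp
            )
    summary = summarize_cohort(decisions, stage2).as_dict()

    # TMB concordance per tumor-fraction class on the tumor-available subset
    tmb_rows = []
    for p in cohort.patients:
        if not p.truth.get("tumor_available"):
            continue
        tcalls = p.mutations.rename(columns={"alt_tumor": "alt_count", "depth_tumor": "depth"})
        tdet = call_mutations(tcalls, thr.limits("de_novo"))
        t_tmb, _ = tmb_fn(int(tdet["detected"].sum()), thr.panel_bp)
        tmb_rows.append(
            {
                "sample": p.sample_id,
                "tumor_tmb": t_tmb,
                "plasma_tmb": stage1[p.sample_id].tmb,
                "tf_class": gz_by_id[p.sample_id].tf_class,
            }
        )
    if tmb_rows:
        write_table(tmb_concordance(pd.DataFrame(tmb_rows)), out / "tmb_concordance.tsv")

    # --- classifier comparison -----------------------------------------
    fm = sizes.loc[pat_ids, ["ratio_short_long"]].copy()
    fm["Z"] = tf.set_index("sample").loc[pat_ids, "Z"]
    labels = {
        sid: (stage1[sid].mvaf is not None and stage1[sid].mvaf >= thr.mvaf_cut) for sid in pat_ids
    }
    fm["high_tf"] = [int(labels[s]) for s in fm.index]
    if fm["high_tf"].nunique() == 2 and fm["high_tf"].value_counts().min() >= 5:
        aucs, _ = compare_feature_sets(
            fm,
            {"Z": ["Z"], "ratio": ["ratio_short_long"], "Z+ratio": ["Z", "ratio_short_long"]},
            seed=cfg.seed,
        )
        write_table(aucs, out / "auc.tsv")
        summary["auc"] = dict(zip(aucs["feature_set"], aucs["auc"]))

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest = {
        "seed": cfg.seed,
        "thresholds": dataclasses.asdict(thr),
        "outputs": {p.name: _sha1(p) for p in sorted(out.glob("*.tsv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %s", summary)
    return summary
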