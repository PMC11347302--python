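"""End-to-end orchestration: ingest -> dedup -> link -> count -> score -> screen.

A :class:`RunConfig` describes one analysis run (real quarterly files or
a synthetic corpus); :func:`run_pipeline` executes every stage, writes
the TSV artifact set and a JSON run manifest with the counts at each
stage (raw reports, deduplicated cases, target-drug reports, reaction
occurrences, distinct PTs, screened terms), and is deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import descriptives as desc
from . import synthetic_data as synth
from .contingency import term_table_frame
from .disproportionality import SignalConfig, compute_signals
from .faers_io import ReportStore, ingest_quarters, load_drug_dictionary, load_pt_to_soc
from .screening import flag_all_four, rank_top, screen

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ConfigFileError"]

log = logging.getLogger("pvsignal")

EXIT_OK = 0
EXIT_DATA_ERROR = 1
EXIT_CONFIG_ERROR = 2


class ConfigFileError(ValueError):
    """A run configuration is unusable (missing file, bad key, bad value)."""


@dataclass
class RunConfig:
    """One pipeline run.

    Exactly one of ``quarters_dir`` (pre-existing FAERS-style files) or
    ``synthetic`` (generator settings) must be given.  Paths are checked
    up front so a bad configuration fails before any compute.
    """

    quarters_dir: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    target_drug: str = synth.TARGET_DRUG
    drug_dict: str | None = None
    pt_to_soc: str | None = None
    roles: tuple[str, ...] = ("PS",)
    counting: str = "reports"
    zero_cell_policy: str = "none"
    yates: bool = True
    min_a: int = 3
    ror_point_threshold: float | None = 3.0
    ranking_key: str = "case_reports"
    top_k: int = 30
    out_dir: str = "pvsignal_out"
    seed: int = 0

    def signal_config(self) -> SignalConfig:
        return SignalConfig(
            zero_cell_policy=self.zero_cell_policy,  # type: ignore[arg-type]
            yates=self.yates,
            min_a=self.min_a,
            ror_point_threshold=self.ror_point_threshold,
        )

    def validate(self) -> None:
        if (self.quarters_dir is None) == (self.synthetic is None):
            raise ConfigFileError("exactly one of quarters_dir / synthetic is required")
        for name in ("quarters_dir", "drug_dict", "pt_to_soc"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigFileError(f"{name} path does not exist: {p}")
        if self.counting not in ("reports", "event_rows"):
            raise ConfigFileError(f"counting must be reports|event_rows, got {self.counting!r}")
        if self.ranking_key not in ("case_reports", "ror"):
            raise ConfigFileError(f"ranking_key must be case_reports|ror, got {self.ranking_key!r}")
        if self.min_a < 0 or self.top_k < 0:
            raise ConfigFileError("min_a and top_k must be non-negative")
        if self.synthetic is not None:
            try:
                self.synthetic.validate()
            except synth.ConfigError as exc:
                raise ConfigFileError(str(exc)) from exc

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        try:
            raw = tomllib.loads(Path(path).read_text())
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise ConfigFileError(f"cannot read config {path}: {exc}") from exc
        syn = raw.pop("synthetic", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigFileError(f"unknown config keys: {sorted(unknown)}")
        if "roles" in raw:
            raw["roles"] = tuple(raw["roles"])
        cfg = cls(**raw)
        if syn is not None:
            try:
                cfg.synthetic = synth.SyntheticConfig.from_dict(syn)
            except (TypeError, synth.ConfigError) as exc:
                raise ConfigFileError(f"bad [synthetic] section: {exc}") from exc
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    store: ReportStore
    manifest: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


def _write_signals(frame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write the artifact set under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "target_drug": config.target_drug}
    artifacts: dict[str, Path] = {}

    # --- ingest -----------------------------------------------------------
    if config.synthetic is not None:
        raw_dir = out / "raw"
        syn_cfg = config.synthetic
        if syn_cfg.seed != config.seed:
            syn_cfg = synth.SyntheticConfig.from_dict(
                {**_syn_dict(syn_cfg), "seed": config.seed}
            )
        written, truth = synth.generate(syn_cfg, raw_dir)
        log.info("simulated %d reports into %s", syn_cfg.n_reports, raw_dir)
        truth_path = raw_dir / "ground_truth.json"
        artifacts["ground_truth"] = truth_path
        drug_dict = load_drug_dictionary(raw_dir / "drug_dict.tsv")
        pt_to_soc = load_pt_to_soc(raw_dir / "pt_to_soc.tsv")
        quarters_dir = raw_dir
    else:
        quarters_dir = Path(config.quarters_dir)
        drug_dict = load_drug_dictionary(config.drug_dict) if config.drug_dict else {}
        pt_to_soc = load_pt_to_soc(config.pt_to_soc) if config.pt_to_soc else {}

    store = ingest_quarters(quarters_dir, drug_dict)
    store.save(out / "store")
    artifacts["store"] = out / "store"
    n_target = len(store.target_case_ids(config.target_drug, config.roles))
    manifest["stages"] = {
        "raw_demo_rows": store.meta.get("n_raw_demo_rows", store.meta["n_demo_rows"]),
        "deduplicated_cases": store.meta["n_demo_rows"],
        "reports_with_reactions": store.n_reports,
        "target_drug_reports": n_target,
        "reaction_occurrences": int(len(store.report_pts)),
        "distinct_pts": int(store.report_pts["pt"].nunique()),
    }
    manifest["ingest_meta"] = store.meta
    log.info("ingest: %s", manifest["stages"])

    # --- statistics at PT and SOC level ----------------------------------
    sig_cfg = config.signal_config()
    screened_sets = {}
    for level in ("PT", "SOC"):
        tables = term_table_frame(
            store, config.target_drug, level=level, pt_to_soc=pt_to_soc,
            counting=config.counting, roles=config.roles,
        )
        results = compute_signals(tables, sig_cfg)
        screened = screen(results, min_a=config.min_a, level=level)
        screened_sets[level] = screened
        frame = screened.to_frame()
        name = "pt_signals.tsv" if level == "PT" else "soc_signals.tsv"
        _write_signals(frame, out / name)
        artifacts[name] = out / name
        manifest["stages"][f"{level.lower()}_terms_observed"] = len(results)
        manifest["stages"][f"{level.lower()}_terms_screened"] = len(screened)
        manifest[f"{level.lower()}_all_four_positive"] = [
            r.term for r in flag_all_four(screened)
        ]

    top = rank_top(screened_sets["PT"], key=config.ranking_key, k=config.top_k)
    top_frame = screened_sets["PT"].to_frame().set_index("term").loc[
        [r.term for r in top]
    ].reset_index()
    _write_signals(top_frame, out / "pt_top.tsv")
    artifacts["pt_top.tsv"] = out / "pt_top.tsv"

    # --- descriptives -----------------------------------------------------
    target_ids = store.target_case_ids(config.target_drug, config.roles)
    target_store = ReportStore(
        reports=store.reports[store.reports["case_id"].isin(target_ids)].reset_index(drop=True),
        report_pts=store.report_pts[store.report_pts["case_id"].isin(target_ids)].reset_index(drop=True),
        report_drugs=store.report_drugs[store.report_drugs["case_id"].isin(target_ids)].reset_index(drop=True),
        meta={},
    )
    summary = desc.summarize(target_store)
    summary.save(out / "descriptives.tsv")
    artifacts["descriptives.tsv"] = out / "descriptives.tsv"
    def _json_safe(triple):
        return [None if v != v else v for v in triple]

    manifest["descriptives"] = {
        "n_target_reports": summary.n_reports,
        "age_median_q1_q3": _json_safe(summary.age_median_q1_q3),
        "onset_median_q1_q3": _json_safe(summary.onset_median_q1_q3),
    }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest.json"] = manifest_path
    return PipelineResult(store=store, manifest=manifest, artifacts=artifacts)


def _syn_dict(cfg: synth.SyntheticConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)
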