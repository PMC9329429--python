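"""Config-driven end-to-end pipeline.

Stages: simulate -> quantify -> pair -> cooccur -> infer-moments -> couple.
A TOML config drives everything; outputs are CSV tables plus a
``manifest.json`` (config snapshot, seed, version, SHA-256 digests of every
output) and a human-readable ``report.txt``.  Stage outputs are pure
functions of (config, seed), so re-running a manifest reproduces them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from burstlink import __version__
from burstlink.burst import burst_summary
from burstlink.cooccurrence import bonferroni, cooccurrence_analysis
from burstlink.coupling import fit_interaction, ks_two_sample
from burstlink.errors import ConfigError
from burstlink.io import write_dataset
from burstlink.moments import subsampled_moments
from burstlink.pairing import assign_cis_pairs, calibrate_threshold, pair_distances
from burstlink.params import (
    Condition,
    GeometryParams,
    KineticsParams,
    NoiseParams,
    ProbeSpec,
    SimulationConfig,
)
from burstlink.simulate import simulate_dataset

log = logging.getLogger("burstlink")

__all__ = ["PipelineConfig", "load_config", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    simulate: SimulationConfig
    tau: float = 2.0
    expression_threshold: int = 5
    per_cell: bool = False
    pair_threshold: float = 1.0
    calibrate_quantile: float = 0.05
    calibrate: bool = True
    levels: tuple[str, ...] = ("cell", "allele")
    moments_n_sub: int = 50
    moments_n_reps: int = 1000
    couple_group_delimiter: str = "_"

    def violations(self) -> list[str]:
        v = self.simulate.violations()
        if self.tau <= 1:
            v.append(f"quantify.tau must be > 1, got {self.tau}")
        if self.expression_threshold < 1:
            v.append("quantify.expression_threshold must be >= 1")
        if self.pair_threshold <= 0:
            v.append(f"pair.threshold must be > 0, got {self.pair_threshold}")
        if not 0 < self.calibrate_quantile < 1:
            v.append("pair.calibrate_quantile must be in (0, 1)")
        for lv in self.levels:
            if lv not in ("cell", "allele"):
                v.append(f"cooccur.levels entries must be 'cell' or 'allele', got {lv!r}")
        if self.moments_n_sub < 2:
            v.append("moments.n_sub must be >= 2")
        if self.moments_n_reps < 1:
            v.append("moments.n_reps must be >= 1")
        return v


def _kinetics_from_dict(d: dict) -> KineticsParams:
    return KineticsParams(**{k: d[k] for k in d if k in KineticsParams.__dataclass_fields__})


def simulation_config_from_dict(sim: dict) -> SimulationConfig:
    kwargs: dict = {}
    for key in ("n_cells_per_replicate", "n_replicates", "ploidy", "seed",
                "single_molecule_intensity", "singles_mean"):
        if key in sim:
            kwargs[key] = sim[key]
    if "conditions" in sim:
        conds = []
        for c in sim["conditions"]:
            c = dict(c)
            label = c.pop("label")
            conds.append(Condition(label, _kinetics_from_dict(c)))
        kwargs["conditions"] = tuple(conds)
    if "geometry" in sim:
        g = dict(sim["geometry"])
        if "chromatic_shift" in g:
            g["chromatic_shift"] = {k: tuple(v) for k, v in g["chromatic_shift"].items()}
        kwargs["geometry"] = GeometryParams(**g)
    if "noise" in sim:
        kwargs["noise"] = NoiseParams(**sim["noise"])
    if "probes" in sim:
        kwargs["probes"] = tuple(ProbeSpec(**p) for p in sim["probes"])
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = simulation_config_from_dict(raw.get("simulate", {}))
    q = raw.get("quantify", {})
    p = raw.get("pair", {})
    co = raw.get("cooccur", {})
    mo = raw.get("moments", {})
    cp = raw.get("couple", {})
    return PipelineConfig(
        simulate=sim,
        tau=q.get("tau", 2.0),
        expression_threshold=q.get("expression_threshold", 5),
        per_cell=q.get("per_cell", False),
        pair_threshold=p.get("threshold", 1.0),
        calibrate_quantile=p.get("calibrate_quantile", 0.05),
        calibrate=p.get("calibrate", True),
        levels=tuple(co.get("levels", ["cell", "allele"])),
        moments_n_sub=mo.get("n_sub", 50),
        moments_n_reps=mo.get("n_reps", 1000),
        couple_group_delimiter=cp.get("group_delimiter", "_"),
    )


def validate_config(path: str | Path) -> list[str]:
    """Parse a pipeline TOML config and return all invariant violations."""
    try:
        cfg = load_config(path)
    except tomllib.TOMLDecodeError as exc:
        return [f"config parse error: {exc}"]
    except (TypeError, KeyError) as exc:
        return [f"config structure error: {exc!r}"]
    return cfg.violations()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _role_probe(config: SimulationConfig, role: str) -> str | None:
    try:
        return config.probe_by_role(role).probe_id
    except KeyError:
        return None


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> Path:
    """Run every stage for a TOML config; returns the output directory.

    Raises :class:`ConfigError` for invalid configs; stage outputs written
    before a failure are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    violations = validate_config(config_path)
    if violations:
        raise ConfigError("; ".join(violations))
    cfg = load_config(config_path)
    sim = cfg.simulate
    written: dict[str, Path] = {}
    report: list[str] = [f"burstlink {__version__} pipeline report", ""]

    log.info("simulate: %d cells x %d conditions", sim.n_cells_total, len(sim.conditions))
    dataset = simulate_dataset(sim)
    written.update(write_dataset(dataset, out))
    report.append(
        f"simulate: {len(dataset.cells)} cells, {len(dataset.spots)} spots, seed {sim.seed}"
    )

    quant = burst_summary(
        dataset,
        tau=cfg.tau,
        ploidy=sim.ploidy,
        count_probe=_role_probe(sim, "gene_exon"),
        expression_threshold=cfg.expression_threshold,
        per_cell=cfg.per_cell,
    )
    written["burst_summary"] = out / "burst_summary.csv"
    quant.summary.to_csv(written["burst_summary"], index=False)
    written["tss"] = out / "tss.csv"
    quant.tss.to_csv(written["tss"], index=False)
    report.append(f"quantify: {len(quant.tss)} TSS bursts called (tau={cfg.tau})")
    report.append("burst fractions per sample:")
    report.append(quant.summary.to_string(index=False, max_rows=60))

    enh_probe = _role_probe(sim, "enhancer")
    gene_probe = _role_probe(sim, "gene_intron") or _role_probe(sim, "gene_exon")
    pairs = None
    threshold = cfg.pair_threshold
    if enh_probe and gene_probe:
        dist_parts = []
        for pa, pb in ((enh_probe, enh_probe), (gene_probe, gene_probe), (enh_probe, gene_probe)):
            dist_parts.append(pair_distances(quant.tss, pa, pb))
        dists = pd.concat(dist_parts, ignore_index=True)
        written["pair_distances"] = out / "pair_distances.csv"
        dists.to_csv(written["pair_distances"], index=False)
        if cfg.calibrate:
            trans = dists.loc[
                dists["pair_type"] != f"{enh_probe}|{gene_probe}", "xy_distance"
            ]
            threshold = calibrate_threshold(
                trans, q=cfg.calibrate_quantile, default=cfg.pair_threshold
            )
        report.append(f"pair: same-allele threshold {threshold:.3f} um")
        pairs = assign_cis_pairs(
            quant.tss[quant.tss["probe_id"] == enh_probe],
            quant.tss[quant.tss["probe_id"] == gene_probe],
            threshold=threshold,
        )
        written["pairs"] = out / "pairs.csv"
        pairs.to_csv(written["pairs"], index=False)
        report.append(f"pair: {len(pairs)} cis-matched enhancer-gene pairs")

        rows = []
        for cond in [c.label for c in sim.conditions]:
            sub = dataset.subset_condition(cond)
            sub_tss = quant.tss[quant.tss["cell_id"].isin(sub.cells["cell_id"])]
            sub_pairs = pairs[pairs["cell_id"].isin(sub.cells["cell_id"])]
            for level in cfg.levels:
                for pa, pb in (
                    [(enh_probe, gene_probe)]
                    + ([(enh_probe, enh_probe), (gene_probe, gene_probe)] if level == "cell" else [])
                ):
                    res = cooccurrence_analysis(
                        sub_tss,
                        sub.cells,
                        pa,
                        pb,
                        level=level,
                        ploidy=sim.ploidy,
                        threshold=threshold,
                        pairs=sub_pairs if level == "allele" else None,
                    )
                    rows.append(
                        {
                            "condition": cond,
                            "level": level,
                            "probe_pair": f"{pa}|{pb}",
                            "observed": res.observed_freq,
                            "expected": res.expected_freq,
                            "ratio": res.ratio,
                            "cmh_stat": res.cmh_statistic,
                            "p": res.p_value,
                            "n_strata": res.n_strata,
                        }
                    )
        cooc = pd.DataFrame(rows)
        valid = cooc["p"].notna()
        cooc["p_adj"] = np.nan
        cooc.loc[valid, "p_adj"] = bonferroni(cooc.loc[valid, "p"])
        written["cooccurrence"] = out / "cooccurrence.csv"
        cooc.to_csv(written["cooccurrence"], index=False)
        report.append("cooccurrence (observed/expected, CMH):")
        report.append(cooc.to_string(index=False, max_rows=60))

    count_probe = _role_probe(sim, "gene_exon")
    if count_probe:
        from burstlink.burst import mature_counts

        counts = mature_counts(dataset, count_probe)
        tab = dataset.cells.assign(count=counts.to_numpy())
        rows = []
        for cond, grp in tab.groupby("condition", sort=True):
            if len(grp) < cfg.moments_n_sub:
                log.warning("condition %s has < n_sub cells; moments skipped", cond)
                continue
            est = subsampled_moments(
                grp["count"], n_sub=cfg.moments_n_sub, n_reps=cfg.moments_n_reps, seed=sim.seed
            )
            rows.append(
                {
                    "condition": cond,
                    "mu": est.mu,
                    "var": est.var,
                    "b_m": est.b_m,
                    "f_m": est.f_m,
                    "n_sub": est.n_sub,
                    "n_reps": est.n_reps,
                }
            )
        moments = pd.DataFrame(rows)
        written["moments"] = out / "moments.csv"
        moments.to_csv(written["moments"], index=False)
        report.append("moment inference (b_m = var/mu, f_m = mu/(b_m-1)):")
        report.append(moments.to_string(index=False))

    # coupling across conditions, grouped by label prefix (e.g. WT_*, KO_*)
    if enh_probe and gene_probe:
        summary = quant.summary
        delim = cfg.couple_group_delimiter
        bf = summary.pivot_table(
            index=["condition", "replicate_id"], columns="probe_id", values="burst_fraction"
        ).reset_index()
        if enh_probe in bf and gene_probe in bf:
            bf["group"] = bf["condition"].astype(str).str.split(delim).str[0]
            pts = bf[(bf[enh_probe] > 0) & (bf[gene_probe] > 0)]
            if pts["group"].nunique() >= 2 and pts.groupby("group").size().min() >= 3:
                fit = fit_interaction(
                    pts.rename(columns={enh_probe: "x", gene_probe: "y"}),
                    log2=True,
                )
                coup = pd.DataFrame(
                    [
                        {
                            "group": g,
                            "slope": fit.slopes[g],
                            "intercept": fit.intercepts[g],
                            "n": fit.n_per_group[g],
                            "interaction_F": fit.f_statistic,
                            "interaction_p": fit.p_value,
                        }
                        for g in fit.slopes
                    ]
                )
                written["coupling"] = out / "coupling.csv"
                coup.to_csv(written["coupling"], index=False)
                report.append("burst-fraction coupling (log2 gene BF ~ log2 enh BF * group):")
                report.append(coup.to_string(index=False))
                if pairs is not None and not pairs.empty:
                    groups = sorted(pts["group"].unique())
                    cellgrp = dataset.cells.assign(
                        group=dataset.cells["condition"].astype(str).str.split(delim).str[0]
                    )
                    merged = pairs.merge(cellgrp[["cell_id", "group"]], on="cell_id")
                    if len(groups) == 2:
                        d1 = merged.loc[merged["group"] == groups[0], "xy_distance"]
                        d2 = merged.loc[merged["group"] == groups[1], "xy_distance"]
                        if len(d1) and len(d2):
                            ks = ks_two_sample(d1, d2)
                            report.append(
                                f"cis-distance KS {groups[0]} vs {groups[1]}: "
                                f"D={ks.statistic:.4f} p={ks.p_value:.3g} "
                                f"(n={ks.n1}, {ks.n2})"
                            )

    manifest = {
        "version": __version__,
        "seed": sim.seed,
        "config": str(Path(config_path).resolve()),
        "config_snapshot": dataclasses.asdict(cfg),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {k: {"path": str(v), "sha256": _digest(v)} for k, v in written.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out
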