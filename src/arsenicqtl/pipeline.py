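"""End-to-end orchestration: simulate/load -> transform -> fit -> scan -> report.

Every stage is a pure function of (inputs, config, seed); intermediates can
be written to disk and re-fed with identical downstream results.  Reported
heritabilities and LODs are rounded half-up to 2 decimals in the tabular
output (full precision is kept in the returned objects).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import linkage as lk
from . import phenotype as ph
from .ibd import GeneticMap, MarkerGenotypes, load_genotypes, load_map, mendelian_check
from .pedigree import Pedigree, kinship_matrix, load_pedigree
from .simulate import SimulationConfig, SimulatedStudy, generate_study
from .varcomp import stratified_heritability

__all__ = ["RunConfig", "load_study", "run_heritability", "run_linkage", "round2"]

TRAITS = ("pct_iAs", "pct_MMA", "pct_DMA")


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, as in the reported tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Single structured configuration driving every pipeline stage."""

    seed: int = 1
    simulation: SimulationConfig | None = None
    pedigree_path: str | None = None
    map_path: str | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    traits: tuple = TRAITS
    covariate_variant: str = "base"
    household: bool = False
    grid_step: float = 2.0
    bit_limit: int = 16
    adjustment_R: int = 1000
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            from .simulate import FamilyTemplate, QTLSpec

            tmpl = sim.pop("template", None)
            qtl = sim.pop("qtl", None)
            sim = SimulationConfig(
                **sim,
                **({"template": FamilyTemplate(**tmpl)} if tmpl else {}),
                **({"qtl": QTLSpec(**qtl)} if qtl else {}),
            )
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StudyData:
    pedigree: Pedigree
    records: pd.DataFrame
    gmap: GeneticMap | None = None
    genotypes: MarkerGenotypes | None = None
    audit: dict = field(default_factory=dict)


def load_study(config: RunConfig) -> StudyData:
    """Simulate per the config, or load the referenced input files."""
    if config.simulation is not None:
        study: SimulatedStudy = generate_study(config.simulation)
        return StudyData(pedigree=study.pedigree, records=study.records,
                         gmap=study.gmap, genotypes=study.genotypes,
                         audit={"source": "simulation",
                                "seed": study.config.seed})
    if config.pedigree_path is None or config.phenotype_path is None:
        raise ValueError("either a simulation block or pedigree/phenotype paths "
                         "are required")
    ped = load_pedigree(config.pedigree_path)
    records = pd.read_csv(config.phenotype_path).set_index("iid")
    records.index = records.index.astype(str)
    gmap = load_map(config.map_path) if config.map_path else None
    genos = load_genotypes(config.genotype_path) if config.genotype_path else None
    return StudyData(pedigree=ped, records=records, gmap=gmap, genotypes=genos,
                     audit={"source": "files"})


def _prepare_traits(data: StudyData, config: RunConfig):
    """Detection filter, percentages, and the two-stage transform per trait."""
    if not config.traits:
        raise ValueError("empty trait list")
    unknown = set(config.traits) - set(TRAITS)
    if unknown:
        raise ValueError(f"unknown trait(s) {sorted(unknown)}; expected {TRAITS}")
    records, tally = ph.filter_detectable(data.records)
    pcts = ph.compute_percentages(records)
    ped = data.pedigree
    keep_ids = [i for i in ped.ids if i in set(pcts.index)]
    sel = np.array([ped.index(i) for i in keep_ids])
    kin = kinship_matrix(ped)
    rel = kin.relationship[np.ix_(sel, sel)]
    pos = {s: k for k, s in enumerate(sel)}
    blocks = []
    for fam in ped.families():
        idx = [pos[i] for i in fam if i in pos]
        if idx:
            blocks.append(np.array(sorted(idx)))
    cov = records.loc[keep_ids]
    out = {}
    for trait in config.traits:
        tt = ph.transform_trait(pcts.loc[keep_ids, trait], cov, rel,
                                variant=config.covariate_variant, blocks=blocks)
        out[trait] = tt
    audit = {"detection_filter": tally,
             "n_analyzed": len(keep_ids),
             "n_excluded_no_pedigree": int(len(pcts) - len(keep_ids))}
    return keep_ids, sel, cov, out, audit


def run_heritability(config: RunConfig):
    """Heritability table (overall + per region) for each requested trait.

    Returns ``(table, details)``: a tidy DataFrame with columns mirroring the
    published layout (trait, stratum, n, h2, se, p_value,
    pct_variance_explained) and the underlying fit objects.
    """
    data = load_study(config)
    keep_ids, sel, cov, transformed, audit = _prepare_traits(data, config)
    ped = data.pedigree

    sub_regions = [ped.region[i] if ped.region else "ALL" for i in sel]
    rows = []
    details = {"audit": audit, "fits": {}}
    for trait, tt in transformed.items():
        res = _stratified_on_subset(tt.final_trait, ped, sel, sub_regions,
                                    household=config.household)
        details["fits"][trait] = res
        for label, entry in res.items():
            if label == "cross_stratum_pairs_dropped":
                continue
            if not entry.get("estimable", False):
                rows.append({"trait": trait, "stratum": label, "n": entry["n"],
                             "h2": np.nan, "se": np.nan, "p_value": np.nan,
                             "pct_variance_explained": np.nan,
                             "note": entry.get("reason", "")})
                continue
            fit = entry["fit"]
            rows.append({
                "trait": trait, "stratum": label, "n": entry["n"],
                "h2": round2(fit.h2),
                "se": round2(fit.h2_se) if fit.h2_se is not None else np.nan,
                "p_value": entry["test"].p_value,
                "pct_variance_explained": round2(
                    100.0 * transformed[trait].pct_variance_explained),
                "note": "",
            })
    table = pd.DataFrame(rows)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "heritability.tsv", sep="\t", index=False)
        with open(out / "heritability_audit.json", "w") as fh:
            json.dump(_jsonable(audit), fh, indent=2)
    return table, details


def _stratified_on_subset(y, ped, sel, strata, household=False):
    """stratified_heritability over the analyzed subset of the pedigree."""
    from .pedigree import household_matrix
    from .varcomp import VarCompModel, fit_ml, heritability_test, _blocks_from_matrix

    kin = kinship_matrix(ped)
    y = np.asarray(y, float)
    strata = np.asarray([str(s) for s in strata])
    out = {}

    def fit_subset(mask, label):
        idx = sel[mask]
        a = kin.relationship[np.ix_(idx, idx)]
        off = a[np.triu_indices(len(idx), k=1)]
        if not np.any(off > 0):
            out[label] = {"estimable": False, "n": int(len(idx)),
                          "reason": "no related pairs in stratum"}
            return
        comps = {"additive": a}
        if household:
            comps["household"] = household_matrix(ped)[np.ix_(idx, idx)]
        model = VarCompModel(y[mask], None, comps, blocks=_blocks_from_matrix(a))
        full = fit_ml(model)
        null = fit_ml(model, fixed={"additive": 0.0})
        out[label] = {"estimable": True, "n": int(len(idx)), "fit": full,
                      "null": null, "test": heritability_test(full, null)}

    mask_all = np.ones(len(y), bool)
    fit_subset(mask_all, "overall")
    for s in sorted(set(strata)):
        fit_subset(strata == s, s)
    ii, jj = np.triu_indices(len(sel), k=1)
    phi_sub = kin.phi[np.ix_(sel, sel)]
    rel = phi_sub[ii, jj] > 0
    out["cross_stratum_pairs_dropped"] = int(np.sum(rel & (strata[ii] != strata[jj])))
    return out


def run_linkage(config: RunConfig, adjust: bool = True, plot: bool = False):
    """Per-trait LOD curves, peak calls, correction constants, adjusted LODs."""
    data = load_study(config)
    if data.gmap is None or data.genotypes is None:
        raise ValueError("linkage requires genotype and map inputs")
    keep_ids, sel, cov, transformed, audit = _prepare_traits(data, config)
    ped = data.pedigree
    _, cleaned, mendel_report = mendelian_check(ped, data.genotypes)
    audit["mendelian"] = mendel_report

    result = {"audit": audit, "traits": {}}
    for trait, tt in transformed.items():
        curves = []
        errors = {}
        for chrom in data.gmap.chromosomes:
            try:
                curves.extend(lk.scan(tt.final_trait, ped, cleaned, data.gmap,
                                      grid_step=config.grid_step,
                                      bit_limit=config.bit_limit,
                                      chromosomes=[chrom], ids=keep_ids))
            except Exception as exc:  # capability errors: report, continue
                errors[str(chrom)] = f"{type(exc).__name__}: {exc}"
        peaks = lk.call_peaks(curves)
        entry = {"curves": curves, "peaks": peaks, "errors": errors}
        if adjust:
            adj = lk.estimate_correction_constant(
                tt.final_trait, ped, R=config.adjustment_R,
                seed=config.seed, trait_name=trait, ids=keep_ids)
            entry["adjustment"] = adj
            entry["adjusted_peaks"] = [
                (p, lk.apply_adjustment(p.lod, adj.constant)) for p in peaks
            ]
        result["traits"][trait] = entry
    if config.outdir:
        _write_linkage(result, config)
        if plot:
            _plot_linkage(result, config)
    return result


def _write_linkage(result: dict, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    report = {}
    for trait, entry in result["traits"].items():
        for curve in entry["curves"]:
            for p, l, m in zip(curve.positions, curve.lod, curve.nearest_markers):
                rows.append({"trait": trait, "chrom": curve.chrom, "pos_cm": p,
                             "lod": l, "nearest_marker": m})
        rep = {"peaks": [dataclasses.asdict(p) for p in entry["peaks"]],
               "errors": entry["errors"]}
        if "adjustment" in entry:
            adj = entry["adjustment"]
            rep["correction_constant"] = adj.constant
            rep["replicates"] = adj.replicates
            rep["chance_findings_unlikely"] = adj.chance_findings_unlikely
            rep["adjusted_peaks"] = [
                {"chrom": p.chrom, "pos_cm": p.pos_cm, "lod_raw": p.lod,
                 "lod_adjusted": a} for p, a in entry["adjusted_peaks"]]
        report[trait] = rep
    pd.DataFrame(rows).to_csv(out / "lod_scan.tsv", sep="\t", index=False)
    with open(out / "linkage_report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)


def _plot_linkage(result: dict, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.outdir)
    chroms = sorted({c.chrom for e in result["traits"].values() for c in e["curves"]},
                    key=str)
    for chrom in chroms:
        fig, ax = plt.subplots(figsize=(7, 4))
        for trait, entry in result["traits"].items():
            for curve in entry["curves"]:
                if curve.chrom == chrom:
                    ax.plot(curve.positions, curve.lod, label=trait)
        ax.axhline(lk.SUGGESTIVE_LOD, ls="--", c="gray", lw=0.8)
        ax.axhline(lk.SIGNIFICANT_LOD, ls=":", c="black", lw=0.8)
        ax.set_xlabel("position (cM)")
        ax.set_ylabel("LOD")
        ax.set_title(f"chromosome {chrom}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"lod_chr{chrom}.png", dpi=120)
        plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
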