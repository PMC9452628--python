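"""Config-driven construct-vs-wildtype comparison pipeline.

Executes the full analysis chain on a set of labelled ensembles (one
reference construct plus any number of insertion constructs):
superposition → geometry observables (RMSF, d_z, kink angle, contacts,
secondary structure) → per-snapshot constraint networks → hydrogen-bond
dilution → stability maps → per-residue energies → construct-vs-
reference differences.  Results are collected in tidy pandas tables and
can be written to a directory of delimited text files together with a
run manifest.

Replicates for every significance test are the subunit × run
combinations; residues are compared on per-chain local indices so that
homotetramer subunits align.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import hcnflex
from hcnflex.constants import CONTACT_CUTOFF
from hcnflex.fits import grand_mean_sem, unpaired_t
from hcnflex.geometry import (count_contacts, dz_displacement, kink_angle,
                              rmsf, ss_content)
from hcnflex.network import (covalent_bonds, detect_hydrogen_bonds,
                             detect_hydrophobic_tethers)
from hcnflex.rigidity import (average_stability_maps, default_ecut_grid,
                              delta_stability, dilute, region_average,
                              stability_map, stability_profile)
from hcnflex.structure import (DomainAnnotation, Ensemble, backbone_mask,
                               read_ensemble, superpose)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComparisonReport", "run_comparison"]


@dataclass
class RunConfig:
    """Inputs and parameters of one comparison run.

    ``ensembles`` maps a construct label to its runs; each run is either
    a multi-model PDB path or an in-memory :class:`Ensemble`.  The
    ``reference`` label plays the wildtype role.  ``stages`` toggles
    "geometry" and "rigidity" independently; the numbers produced by an
    enabled stage do not depend on which other stages run.
    """

    ensembles: dict[str, list] = field(default_factory=dict)
    annotation: DomainAnnotation | str | Path | None = None
    reference: str = "0G"
    ecut_grid: np.ndarray | None = None
    contact_cutoff: float = CONTACT_CUTOFF
    alpha: float = 0.05
    superpose_on: str = "S6"
    max_frames: int | None = None
    output_dir: str | Path | None = None
    seed: int = 0
    stages: tuple[str, ...] = ("geometry", "rigidity")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        grid = raw.get("ecut_grid")
        if isinstance(grid, dict):
            grid = default_ecut_grid(grid.get("start", -0.1),
                                     grid.get("stop", -6.0),
                                     grid.get("step", 0.1))
        elif grid is not None:
            grid = np.asarray(grid, dtype=float)
        base = Path(path).parent
        ens = {label: [str(base / p) for p in paths]
               for label, paths in raw["ensembles"].items()}
        ann = raw.get("annotation")
        return cls(
            ensembles=ens,
            annotation=str(base / ann) if ann else None,
            reference=raw.get("reference", "0G"),
            ecut_grid=grid,
            contact_cutoff=float(raw.get("contact_cutoff", CONTACT_CUTOFF)),
            alpha=float(raw.get("alpha", 0.05)),
            superpose_on=raw.get("superpose_on", "S6"),
            max_frames=raw.get("max_frames"),
            output_dir=raw.get("output"),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ("geometry", "rigidity"))),
        )


@dataclass
class ComparisonReport:
    """Tidy result tables of one comparison run."""

    rmsf: pd.DataFrame | None = None
    dz: pd.DataFrame | None = None
    kink: pd.DataFrame | None = None
    contacts: pd.DataFrame | None = None
    ss: pd.DataFrame | None = None
    delta_stability: pd.DataFrame | None = None
    region_averages: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("rmsf", "dz", "kink", "contacts", "ss",
                     "delta_stability", "region_averages"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                          float_format="%.6g")
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh)


# ---------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------

def _load_ensembles(config: RunConfig) -> dict[str, list[Ensemble]]:
    out: dict[str, list[Ensemble]] = {}
    for label, runs in config.ensembles.items():
        loaded = []
        for r in runs:
            ens = r if isinstance(r, Ensemble) else read_ensemble(r)
            if config.max_frames is not None and len(ens) > config.max_frames:
                ens = Ensemble(ens.snapshots[:config.max_frames],
                               dict(ens.metadata))
            loaded.append(ens)
        out[label] = loaded
    return out


def _chain_residues(snapshot, annotation: DomainAnnotation) -> dict[str, np.ndarray]:
    """Ordered internal residue indices per chain of the subunit cycle."""
    chains = annotation.subunit_order or list(dict.fromkeys(snapshot.chain_id))
    out = {}
    for c in chains:
        out[c] = np.sort(np.unique(
            snapshot.residue_index[snapshot.chain_id == c]))
    sizes = {len(v) for v in out.values()}
    if len(sizes) != 1:
        raise ValueError("subunits differ in residue count; cannot align")
    return out


def _per_subunit_rmsf(ensemble: Ensemble, annotation, selection) -> list[np.ndarray]:
    sup = superpose(ensemble, selection)
    vals = rmsf(sup)
    chains = _chain_residues(ensemble[0], annotation)
    return [vals[res] for res in chains.values()]


# ---------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------

def run_comparison(config: RunConfig) -> ComparisonReport:
    """Run the full construct-vs-reference comparison.

    Requires at least two constructs, one of which carries the
    ``config.reference`` label.  Deterministic given the config.
    """
    if len(config.ensembles) < 2:
        raise ValueError("need >= 2 constructs (reference + construct)")
    if config.reference not in config.ensembles:
        raise ValueError(f"reference label {config.reference!r} missing")
    annotation = config.annotation
    if not isinstance(annotation, DomainAnnotation):
        if annotation is None:
            raise ValueError("config.annotation is required")
        annotation = DomainAnnotation.from_yaml(annotation)
    grid = (config.ecut_grid if config.ecut_grid is not None
            else default_ecut_grid())

    ensembles = _load_ensembles(config)
    ref_label = config.reference
    report = ComparisonReport(manifest={
        "package_version": hcnflex.__version__,
        "reference": ref_label,
        "constructs": sorted(ensembles),
        "n_runs": {k: len(v) for k, v in ensembles.items()},
        "n_frames": {k: [len(e) for e in v] for k, v in ensembles.items()},
        "ecut_grid": [float(x) for x in grid],
        "contact_cutoff": float(config.contact_cutoff),
        "alpha": float(config.alpha),
        "superpose_on": config.superpose_on,
        "contact_definition": "residue pair with >= 1 heavy-atom pair "
                              f"within {config.contact_cutoff} A",
        "seed": config.seed,
        "stages": list(config.stages),
    })

    first = ensembles[ref_label][0][0]
    chains = _chain_residues(first, annotation)
    n_local = len(next(iter(chains.values())))

    # ---------------- geometry stage --------------------------------
    if "geometry" in config.stages:
        logger.info("geometry stage: RMSF, d_z, kink, contacts, SS")
        rmsf_reps: dict[str, list[np.ndarray]] = {}
        rows_dz, rows_kink, rows_con, rows_ss = [], [], [], []
        for label, runs in sorted(ensembles.items()):
            reps = []
            for run_id, ens in enumerate(runs):
                sel = backbone_mask(ens[0],
                                    annotation.residues(ens[0],
                                                        config.superpose_on))
                reps.extend(_per_subunit_rmsf(ens, annotation, sel))

                per_sub_dz: dict[str, list[float]] = {}
                per_sub_kink: dict[str, list[float]] = {}
                for snap in ens:
                    for c, v in dz_displacement(snap, annotation).items():
                        per_sub_dz.setdefault(c, []).append(v)
                    for c in annotation.subunit_order:
                        per_sub_kink.setdefault(c, []).append(kink_angle(
                            snap,
                            annotation.residues(snap, "S6", chain=c),
                            annotation.residues(snap, "CL", chain=c)))
                for c in per_sub_dz:
                    rows_dz.append({
                        "construct": label, "run": run_id, "subunit": c,
                        "mean_dz_A": float(np.mean(per_sub_dz[c])),
                        "peak_dz_A": float(np.max(per_sub_dz[c])),
                        "n_frames": len(per_sub_dz[c])})
                    rows_kink.append({
                        "construct": label, "run": run_id, "subunit": c,
                        "mean_kink_deg": float(np.mean(per_sub_kink[c])),
                        "n_frames": len(per_sub_kink[c])})

                if "S4" in annotation.ranges:
                    counts = []
                    for snap in ens:
                        for c in annotation.subunit_order:
                            prev = annotation.preceding_subunit(c)
                            counts.append(count_contacts(
                                snap,
                                annotation.residues(snap, "S4", chain=c),
                                annotation.residues(snap, "CL", chain=prev),
                                cutoff=config.contact_cutoff))
                    counts = np.asarray(counts)
                    rows_con.append({
                        "construct": label, "run": run_id,
                        "mean": float(counts.mean()),
                        "q25": float(np.percentile(counts, 25)),
                        "median": float(np.median(counts)),
                        "q75": float(np.percentile(counts, 75)),
                        "n": len(counts)})

                for region_name in ("insertion_flanks", "insertion"):
                    if region_name in annotation.ranges:
                        frac, sem = ss_content(
                            ens, annotation.residues(ens[0], region_name))
                        rows_ss.append({
                            "construct": label, "run": run_id,
                            "region": region_name, "fraction": frac,
                            "sem": sem})
            rmsf_reps[label] = reps

        ref_mat = np.stack(rmsf_reps[ref_label])
        rows = []
        for label, reps in sorted(rmsf_reps.items()):
            mat = np.stack(reps)
            mean = np.nanmean(mat, axis=0)
            sem = (np.nanstd(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0])
                   if mat.shape[0] > 1 else np.full(n_local, np.nan))
            for r in range(n_local):
                row = {"construct": label, "residue": r + 1,
                       "rmsf_A": float(mean[r]), "sem_A": float(sem[r]),
                       "n": int(mat.shape[0]), "p_vs_ref": np.nan,
                       "significant": False}
                if label != ref_label and mat.shape[0] > 1 \
                        and ref_mat.shape[0] > 1:
                    _, p = unpaired_t(ref_mat[:, r], mat[:, r])
                    row["p_vs_ref"] = float(p)
                    row["significant"] = bool(p < config.alpha)
                rows.append(row)
        report.rmsf = pd.DataFrame(rows)
        report.dz = pd.DataFrame(rows_dz)
        report.kink = pd.DataFrame(rows_kink)
        report.contacts = pd.DataFrame(rows_con) if rows_con else None
        report.ss = pd.DataFrame(rows_ss) if rows_ss else None

        for name, df, col in (("dz_grand_mean", report.dz, "mean_dz_A"),
                              ("kink_grand_mean", report.kink,
                               "mean_kink_deg")):
            summary = {}
            for label in sorted(ensembles):
                sub = df[df.construct == label]
                runs = [g[col].to_numpy() for _, g in sub.groupby("run")]
                gm, sem = grand_mean_sem(runs)
                summary[label] = {"mean": gm, "sem": sem}
            report.manifest[name] = summary

    # ---------------- rigidity stage --------------------------------
    if "rigidity" in config.stages:
        logger.info("rigidity stage: networks, dilution, stability maps")
        profiles: dict[str, list[np.ndarray]] = {}
        for label, runs in sorted(ensembles.items()):
            reps = []
            for run_id, ens in enumerate(runs):
                cov = covalent_bonds(ens[0])
                maps = []
                for k, snap in enumerate(ens):
                    try:
                        hb = detect_hydrogen_bonds(snap, covalent=cov)
                        te = detect_hydrophobic_tethers(snap, covalent=cov)
                        dil = dilute(snap, hb, te, grid, covalent=cov)
                        maps.append(stability_map(
                            dil, snap, contact_cutoff=config.contact_cutoff))
                    except Exception as exc:
                        raise RuntimeError(
                            f"rigidity stage failed for construct {label!r}, "
                            f"run {run_id}, snapshot {k}: {exc}") from exc
                prof = stability_profile(average_stability_maps(maps))
                for c, res in _chain_residues(ens[0], annotation).items():
                    reps.append(prof.E_i[res])
            profiles[label] = reps

        rows, region_rows = [], []
        region_names = [n for n in ("S4", "upper_pore", "S6", "CL",
                                    "selectivity_filter", "gate")
                        if n in annotation.ranges]
        c0 = (annotation.subunit_order[0] if annotation.subunit_order
              else next(iter(chains)))
        for label in sorted(ensembles):
            if label == ref_label:
                continue
            delta = delta_stability(profiles[ref_label], profiles[label],
                                    alpha=config.alpha)
            for r in range(n_local):
                rows.append({"construct": label, "residue": r + 1,
                             "dE_kcal_mol": float(delta.dE_i[r]),
                             "dE_raw_kcal_mol": float(delta.dE_i_raw[r]),
                             "p": float(delta.p_i[r]),
                             "significant": bool(delta.significant_i[r]),
                             "n_ref": len(profiles[ref_label]),
                             "n_con": len(profiles[label])})
            for rname in region_names:
                res_global = annotation.residues(first, rname, chain=c0)
                local = np.searchsorted(chains[c0], res_global)
                m, sd = region_average(delta, local)
                region_rows.append({"construct": label, "region": rname,
                                    "mean_dE_kcal_mol": m, "sd": sd})
        report.delta_stability = pd.DataFrame(rows)
        report.region_averages = (pd.DataFrame(region_rows)
                                  if region_rows else None)

    if config.output_dir is not None:
        report.write(config.output_dir)
    return report
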