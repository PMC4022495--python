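"""Orchestration of the full apo-vs-holo comparative analysis.

``run_analysis`` executes every stage the package implements — load,
per-chain RMSDs, closure analyses, interface areas, contact censuses with
swap classification, ligand-pocket inventory, sequence metrics, backbone
stereochemistry, optional ITC fit — and assembles a JSON-serialisable
report.  A stage failure is recorded under its stage name and independent
stages continue.

Inputs are either deposited coordinate files (``apo_path`` / ``holo_path``)
or, absent those, the deterministic synthetic open/closed swapped-dimer
fixtures, so the pipeline is exercisable end to end without downloads.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .contacts import SwapAnnotation, all_contacts, classify_swap_interfaces, ligand_pocket_contacts, salt_bridges
from .sasa import buried_area
from .seqcomp import SequenceRecord, composition, hinge_motif_check, read_fasta, stoichiometry, theoretical_mass
from .stereochem import backbone_geometry, psi_window_stats
from .structure import DomainDefinition, Structure, parse_ranges, read_pdb, sequence_from_chain
from .superpose import closure_analysis, rmsd
from .synth import ToySpec, apply_domain_rotation, make_swapped_dimer, make_two_lobe_monomer

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "apo_path", "holo_path", "chain_map", "lobe1", "lobe2", "hinge", "swapped",
    "main_body", "ligand_name", "salt_bridge_cutoff", "hbond_dmax", "hbond_angle_min",
    "hydrophobic_cutoff", "sasa_probe", "sasa_n_points", "psi_windows",
    "sequence_fasta", "sequence_first_number", "mals_masses_kda", "monomer_mass_da",
    "itc_heats_tsv", "itc_design", "seed", "synthetic_angle_deg", "synthetic_spec",
}


@dataclass
class AnalysisConfig:
    """Validated configuration; unknown keys are rejected fail-fast."""

    apo_path: str | None = None
    holo_path: str | None = None
    chain_map: dict = field(default_factory=lambda: {"apo": ["A", "B"], "holo": ["A", "B"]})
    # residue-range strings on a reference chain; re-targeted per chain
    lobe1: str = "A:23-110,A:210-231"
    lobe2: str = "A:116-203"
    hinge: tuple[int, int] = (232, 236)
    swapped: tuple[int, int] = (237, 246)
    main_body: tuple[int, int] = (20, 233)
    ligand_name: str = "ARG"
    salt_bridge_cutoff: float = 4.0
    hbond_dmax: float = 3.5
    hbond_angle_min: float = 120.0
    hydrophobic_cutoff: float = 4.5
    sasa_probe: float = 1.4
    sasa_n_points: int = 960
    psi_windows: list = field(default_factory=lambda: [(75.0, 105.0), (135.0, 165.0)])
    sequence_fasta: str | None = None
    sequence_first_number: int = 20
    mals_masses_kda: dict = field(default_factory=lambda: {"holo": 50.3, "apo": 49.6})
    monomer_mass_da: float | None = None
    itc_heats_tsv: str | None = None
    itc_design: dict = field(default_factory=dict)
    seed: int = 0
    synthetic_angle_deg: float = 84.0
    synthetic_spec: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _contact_row(c) -> dict:
    return {
        "kind": c.kind,
        "chain1": c.res1[0], "res1": c.res1[1], "name1": c.res1[2], "atom1": c.atom1,
        "chain2": c.res2[0], "res2": c.res2[1], "name2": c.res2[2], "atom2": c.atom2,
        "distance_A": round(c.distance, 3),
        "flags": list(c.flags),
    }


def _synthetic_pair(cfg: AnalysisConfig) -> tuple[Structure, Structure, dict]:
    """Open (apo-like) and closed (holo-like) synthetic swapped dimers.

    The closed form is generated by rotating lobe 2 of the monomer by the
    configured closure angle about an axis through the inter-lobe linker
    before dimerisation, so the apo-vs-holo closure measured downstream has
    a known ground truth.
    """
    spec = ToySpec(seed=cfg.seed, **cfg.synthetic_spec)
    mono_open, domains = make_two_lobe_monomer(spec)
    linker_lo = domains["linker"].ranges[0][1]
    pivot = mono_open.chains[0].residue(linker_lo).atom("CA").pos
    axis = np.array([0.0, 0.0, 1.0])
    moving = DomainDefinition("moving", [("A", domains["lobe2"].ranges[0][1],
                                          domains["tail"].ranges[0][2])])
    mono_closed = apply_domain_rotation(mono_open, moving, axis, cfg.synthetic_angle_deg, pivot)
    apo, ddom = make_swapped_dimer(mono_open, domains)
    holo, _ = make_swapped_dimer(mono_closed, domains)
    meta = {
        "domains": {k: d.ranges for k, d in ddom.items()},
        "applied_closure_deg": cfg.synthetic_angle_deg,
        "monomer_domains": domains,
    }
    return apo, holo, meta


def run_analysis(config: AnalysisConfig | dict) -> dict:
    """Execute the full comparative pipeline and return the report dict."""
    cfg = config if isinstance(config, AnalysisConfig) else AnalysisConfig.from_dict(config)
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "config_digest": cfg.digest(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "stages": {},
        "errors": {},
    }

    synthetic = cfg.apo_path is None and cfg.holo_path is None

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
                report["stages"][name] = _jsonable(out)
                logger.info("stage %-24s done in %.2fs", name, time.perf_counter() - t0)
            except Exception as exc:  # record and continue with independent stages
                report["errors"][name] = f"{type(exc).__name__}: {exc}"
                logger.warning("stage %s failed: %s", name, exc)
            return fn
        return deco

    structures: dict[str, Structure] = {}
    meta: dict = {}

    @stage("load")
    def _load():
        if synthetic:
            apo, holo, m = _synthetic_pair(cfg)
            structures["apo"], structures["holo"] = apo, holo
            meta.update(m)
            return {"mode": "synthetic",
                    "domains": m["domains"],
                    "applied_closure_deg": m["applied_closure_deg"],
                    "monomer_domains": {k: d.ranges for k, d in m["monomer_domains"].items()}}
        out = {"mode": "files"}
        if cfg.apo_path:
            structures["apo"] = read_pdb(Path(cfg.apo_path))
            out["apo"] = {"path": cfg.apo_path, "chains": structures["apo"].chain_ids}
        if cfg.holo_path:
            structures["holo"] = read_pdb(Path(cfg.holo_path))
            out["holo"] = {"path": cfg.holo_path, "chains": structures["holo"].chain_ids}
        return out

    # ----- domain definitions in the analysis frame ------------------------
    if synthetic and "monomer_domains" in meta:
        md = meta["monomer_domains"]
        lobe1 = md["lobe1"]
        lobe2_full = DomainDefinition("lobe2+tail", [("A", md["lobe2"].ranges[0][1], md["tail"].ranges[0][2])])
        lobe2 = md["lobe2"]
        hinge_rng = (md["hinge"].ranges[0][1], md["hinge"].ranges[0][2])
        swapped_rng = (md["tail"].ranges[0][1], md["tail"].ranges[0][2])
        body_rng = (md["main_body"].ranges[0][1], md["main_body"].ranges[0][2])
        full = DomainDefinition("full", [("A", md["lobe1"].ranges[0][1], md["tail"].ranges[0][2])])
    else:
        lobe1 = parse_ranges(cfg.lobe1, "lobe1")
        lobe2 = parse_ranges(cfg.lobe2, "lobe2")
        lobe2_full = lobe2
        hinge_rng, swapped_rng, body_rng = tuple(cfg.hinge), tuple(cfg.swapped), tuple(cfg.main_body)
        full = DomainDefinition("full", [("A", body_rng[0], swapped_rng[1])])
    annotation = SwapAnnotation(swapped_segment=tuple(swapped_rng), hinge=tuple(hinge_rng),
                                main_body=tuple(body_rng))

    def chains_of(which: str) -> list[str]:
        if synthetic:
            return ["A", "B"]
        return list(cfg.chain_map.get(which, structures[which].chain_ids[:2]))

    # ----- RMSD table ------------------------------------------------------
    @stage("rmsd")
    def _rmsd():
        out = {}
        for which in ("apo", "holo"):
            if which not in structures:
                continue
            st = structures[which]
            a, b = chains_of(which)[:2]
            out[f"{which}_chain_{a}_vs_{b}_ca"] = rmsd(
                st, st, full.on_chain(a), full.on_chain(b), ("CA",), fit=True)
            out[f"{which}_chain_{a}_vs_{b}_backbone"] = rmsd(
                st, st, full.on_chain(a), full.on_chain(b), ("N", "CA", "C", "O"), fit=True)
        if "apo" in structures and "holo" in structures:
            sa, sh = structures["apo"], structures["holo"]
            ca_apo, ch_holo = chains_of("apo")[0], chains_of("holo")[0]
            out["apo_vs_holo_monomer_ca"] = rmsd(
                sa, sh, full.on_chain(ca_apo), full.on_chain(ch_holo), ("CA",), fit=True)
            out["apo_vs_holo_lobe1_ca"] = rmsd(
                sa, sh, lobe1.on_chain(ca_apo), lobe1.on_chain(ch_holo), ("CA",), fit=True)
            out["apo_vs_holo_lobe2_ca"] = rmsd(
                sa, sh, lobe2.on_chain(ca_apo), lobe2.on_chain(ch_holo), ("CA",), fit=True)
        return out

    # ----- closure analyses ------------------------------------------------
    @stage("closure")
    def _closure():
        out = {}

        def record(tag, res):
            out[tag] = {"angle_deg": res.angle, "axis": res.axis,
                        "fixed_rmsd_A": res.fixed_rmsd, "moving_rmsd_A": res.moving_rmsd}

        if "apo" in structures:
            st = structures["apo"]
            a, b = chains_of("apo")[:2]
            record("apo_chainA_vs_chainB",
                   closure_analysis(st, st, lobe1.on_chain(a), lobe2_full.on_chain(a),
                                    fixed_domain_b=lobe1.on_chain(b),
                                    moving_domain_b=lobe2_full.on_chain(b)))
        if "apo" in structures and "holo" in structures:
            sa, sh = structures["apo"], structures["holo"]
            for ca_ in chains_of("apo")[:2]:
                for ch_ in chains_of("holo")[:2]:
                    record(f"apo_{ca_}_vs_holo_{ch_}",
                           closure_analysis(sa, sh, lobe1.on_chain(ca_), lobe2_full.on_chain(ca_),
                                            fixed_domain_b=lobe1.on_chain(ch_),
                                            moving_domain_b=lobe2_full.on_chain(ch_)))
            angles = [v["angle_deg"] for k, v in out.items() if k.startswith("apo_") and "_vs_holo_" in k]
            if len(angles) >= 2:
                # the apo-chain flexibility expressed as a closure-angle difference
                out["apo_closure_angle_difference_deg"] = float(
                    abs(max(angles) - min(angles)))
        return out

    # ----- buried interface areas ------------------------------------------
    @stage("interface_area")
    def _area():
        out = {}
        for which in ("apo", "holo"):
            if which not in structures:
                continue
            a, b = chains_of(which)[:2]
            rep = buried_area(structures[which], [a], [b],
                              probe=cfg.sasa_probe, n_points=cfg.sasa_n_points)
            out[which] = {
                "buried_total_A2": rep.buried_total,
                "interface_area_A2": rep.interface_area,
                "buried_per_side_A2": rep.buried_per_side,
                "n_interface_residues": {k: len(v) for k, v in rep.interface_residues.items()},
            }
        if "apo" in out and "holo" in out:
            out["apo_minus_holo_A2"] = out["apo"]["buried_total_A2"] - out["holo"]["buried_total_A2"]
        return out

    # ----- contact censuses and swap classification ------------------------
    @stage("contacts")
    def _contacts():
        out = {}
        for which in ("apo", "holo"):
            if which not in structures:
                continue
            st = structures[which]
            inter = all_contacts(st, scope="inter")
            swap = classify_swap_interfaces(st, annotation, inter)
            # the salt-bridge thermostability count, reported per chain since
            # the literature convention (which chain, which cutoff) varies
            intra = salt_bridges(st, cutoff=cfg.salt_bridge_cutoff, scope="intra")
            intra_bridges = {
                cid: sum(1 for c in intra if c.res1[0] == cid)
                for cid in chains_of(which)[:2]
            }
            out[which] = {
                "inter_chain_contacts": [_contact_row(c) for c in inter],
                "swap_classification": swap.counts,
                "c_interface": [_contact_row(c) for c in swap.c_interface],
                "o_interface": [_contact_row(c) for c in swap.o_interface],
                "intra_chain_salt_bridges": intra_bridges,
            }
        return out

    # ----- ligand pocket (holo) --------------------------------------------
    @stage("ligand_pocket")
    def _pocket():
        if "holo" not in structures:
            return {"skipped": "no holo structure"}
        st = structures["holo"]
        ligands = [(cid, r) for cid, r in st.hetero_residues() if r.name == cfg.ligand_name]
        if not ligands:
            return {"skipped": f"no hetero residue named {cfg.ligand_name!r}"}
        out = {}
        for cid, res in ligands:
            cts, lig_sasa = ligand_pocket_contacts(st, (cid, res.number))
            out[f"{cid}:{res.number}"] = {
                "contacts": [_contact_row(c) for c in cts],
                "ligand_sasa_A2": lig_sasa,
                "solvent_inaccessible": lig_sasa < 5.0,
            }
        return out

    # ----- sequence metrics -------------------------------------------------
    @stage("sequence")
    def _sequence():
        if cfg.sequence_fasta:
            rec = read_fasta(cfg.sequence_fasta, first_number=cfg.sequence_first_number)
        elif structures:
            which = "apo" if "apo" in structures else "holo"
            seq, first = sequence_from_chain(structures[which].protein_chains()[0])
            rec = SequenceRecord(seq.replace("X", "A"), first_number=first)
        else:
            return {"skipped": "no sequence source"}
        comp = composition(rec)
        mass = theoretical_mass(rec)
        monomer = cfg.monomer_mass_da or mass
        masses = cfg.mals_masses_kda
        if synthetic:
            # demonstrate the mass -> oligomer-state assignment on the toy
            masses = {"synthetic_dimer": 2.0 * monomer / 1000.0}
        stoich = {}
        for label, kda in masses.items():
            ratio, n, ok = stoichiometry(kda, monomer)
            stoich[label] = {"measured_kda": kda, "ratio": ratio, "n": n, "unambiguous": ok}
        hinge = None
        try:
            hinge = hinge_motif_check(rec, tuple(hinge_rng))
        except IndexError:
            pass
        return {
            "length": comp.length,
            "pct_charged": comp.pct_charged,
            "pct_polar": comp.pct_polar,
            "theoretical_mass_da": round(mass),
            "monomer_mass_used_da": monomer,
            "stoichiometry": stoich,
            "hinge_motif": hinge,
        }

    # ----- backbone stereochemistry ----------------------------------------
    @stage("stereochemistry")
    def _stereo():
        out = {}
        for which in ("apo", "holo"):
            if which not in structures:
                continue
            geoms = backbone_geometry(structures[which])
            ncac_h = [g.ncac for g in geoms if g.ss == "H" and g.ncac is not None]
            ncac_e = [g.ncac for g in geoms if g.ss == "E" and g.ncac is not None]
            windows = {}
            for q in ("ncac", "delta_omega", "theta_c"):
                for w in psi_window_stats(geoms, q, cfg.psi_windows):
                    windows[f"{q}_{w.window[0]:g}_{w.window[1]:g}"] = {
                        "n": w.n, "mean": w.mean, "sd": w.sd}
            out[which] = {
                "n_residues": len(geoms),
                "ncac_mean_helix": float(np.mean(ncac_h)) if ncac_h else None,
                "ncac_mean_strand": float(np.mean(ncac_e)) if ncac_e else None,
                "psi_windows": windows,
            }
        return out

    # ----- optional ITC fit -------------------------------------------------
    @stage("itc")
    def _itc():
        from .itc import ItcDesign, fit_one_site, Isotherm, read_heats_tsv, _concentrations

        if not cfg.itc_heats_tsv:
            return {"skipped": "no heats table provided"}
        design = ItcDesign(**cfg.itc_design) if cfg.itc_design else ItcDesign()
        heats = read_heats_tsv(cfg.itc_heats_tsv)
        mt, xt = _concentrations(design, "linear")
        fit = fit_one_site(Isotherm(heats, xt / mt), design)
        return {
            "n": fit.params.n, "k_d_molar": fit.params.k_d, "dh_kcal_mol": fit.params.dh,
            "q_offset_ucal": fit.params.q_offset, "stderr": fit.stderr,
            "converged": fit.converged, "no_binding": fit.no_binding,
        }

    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json plus a terse human-readable report.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    lines = [f"analysis report (schema v{report['schema_version']})",
             f"config digest: {report['provenance']['config_digest']}", ""]
    for name, payload in report["stages"].items():
        lines.append(f"[{name}]")
        lines.append(json.dumps(payload, indent=1, default=str)[:4000])
        lines.append("")
    for name, err in report.get("errors", {}).items():
        lines.append(f"[ERROR {name}] {err}")
    (out / "report.txt").write_text("\n".join(lines))
    return out / "report.json"
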