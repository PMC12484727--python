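"""Study-design orchestration at phantom scale.

Four experiments mirror the published study design on synthetic phantoms:

* **complexity** — heterogeneous (WM/GM/CSF) vs homogeneous brain on the
  identical skull-stripped mesh, exterior surface fixed;
* **bc** — five boundary conditions (skull base; 120 mm neck cylinder;
  500 mm spine cylinder; fMRI-style base+back+sides; skull stripped with
  the whole exterior fixed) under one consistent material set;
* **csf-sweep** — CSF Young's modulus swept over the published grid, all
  other properties fixed, compared against the stiffest (2.19 MPa) case;
* **ratio** — the stiffness-ratio hypothesis: scaling every region's E by
  one factor c leaves mode shapes exactly invariant (MAC = 1) and
  multiplies every frequency by √c, while mixed brain/CSF pairs with
  similar stiffness ratios are compared descriptively.

Phantom meshes here are ~10⁴ elements; absolute frequencies are mesh- and
scale-specific, so the experiments assert trends and exact laws, never the
absolute Hz values of anatomical models.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import apply_dirichlet, assemble
from .compare import ModeComparison, compare, nrfd, plot_comparison
from .materials import BRAIN_STIFFNESS, CSF_E_GRID, MaterialSet
from .mesh import BRAIN_REGIONS, LabeledMesh
from .modal import ModalResult, expand_to_full, frequency_table, solve_modes
from .phantom import PhantomConfig, attach_cylinder, build_layered_phantom, strip_skull

__all__ = [
    "ExperimentSpec",
    "run_complexity_comparison",
    "run_bc_comparison",
    "run_csf_sweep",
    "run_ratio_hypothesis",
    "run_all",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Shared configuration for the experiment suite.

    ``nu_cap`` caps Poisson's ratios (default 0.49) to avoid volumetric
    locking of the near-incompressible CSF on linear tetrahedra; pass
    ``None`` for the faithful published value of 0.4999.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_modes: int = 25
    pairing_threshold: float = 0.5
    seed: int = 0
    nu_cap: float | None = 0.49
    mass: str = "consistent"

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


# -- shared machinery -----------------------------------------------------


def _solve_scenario(
    mesh: LabeledMesh,
    materials: MaterialSet,
    node_sets,
    spec: ExperimentSpec,
) -> tuple[ModalResult, object]:
    system = assemble(mesh, materials.with_nu_cap(spec.nu_cap), mass=spec.mass)
    system = apply_dirichlet(system, mesh, node_sets)
    result = solve_modes(system, n_modes=spec.n_modes, seed=spec.seed)
    return result, system


def _coord_keys(nodes: np.ndarray) -> list[bytes]:
    return [row.tobytes() for row in np.round(nodes, 6)]


def _restricted_shapes(
    mesh_a: LabeledMesh, res_a: ModalResult,
    mesh_b: LabeledMesh, res_b: ModalResult,
    regions=BRAIN_REGIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Mode shapes of both results on the shared brain nodes.

    Nodes are matched by coordinates (identical across scenario meshes
    derived from one phantom); skull/appendage DOFs are excluded so that
    skull-stripped and full-head scenarios are comparable.
    """
    nodes_a = np.concatenate(
        [mesh_a.region_nodes(r) for r in regions if r in mesh_a.regions])
    nodes_a = np.unique(nodes_a)
    key_to_b = {k: i for i, k in enumerate(_coord_keys(mesh_b.nodes))}
    keys_a = _coord_keys(mesh_a.nodes[nodes_a])
    pairs = [(a, key_to_b[k]) for a, k in zip(nodes_a, keys_a) if k in key_to_b]
    if not pairs:
        raise ValueError("meshes share no brain nodes; cannot compare")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    full_a = expand_to_full(res_a).reshape(mesh_a.n_nodes, 3, -1)
    full_b = expand_to_full(res_b).reshape(mesh_b.n_nodes, 3, -1)
    sa = full_a[ia].reshape(3 * len(ia), -1)
    sb = full_b[ib].reshape(3 * len(ib), -1)
    return sa, sb


def _cross_mesh_compare(
    mesh_a, res_a, mesh_b, res_b, threshold, labels,
) -> ModeComparison:
    sa, sb = _restricted_shapes(mesh_a, res_a, mesh_b, res_b)
    comp = compare(sa, sb, threshold=threshold, labels=labels)
    comp.freqs_a = res_a.frequencies_hz
    comp.freqs_b = res_b.frequencies_hz
    comp.nrfd = np.array([
        nrfd(res_a.frequencies_hz[i], res_b.frequencies_hz[k])
        for i, k, _ in comp.pairing
    ])
    return comp


def _count_distinct_shapes(entries, threshold: float) -> int:
    """Greedy distinct-mode-shape count across scenarios.

    ``entries`` is a list of (scenario, shape-matrix); a mode joins an
    existing shape class when its MAC to the class representative reaches
    ``threshold``, else founds a new class.  The count depends on the
    disclosed threshold.
    """
    from .compare import mac

    reps: list[np.ndarray] = []
    for _scenario, shapes in entries:
        for i in range(shapes.shape[1]):
            v = shapes[:, i]
            if not any(mac(v, r) >= threshold for r in reps):
                reps.append(v)
    return len(reps)


def _write_report(outdir, name: str, tables: dict, summary: dict,
                  comparisons: dict | None = None) -> dict:
    files = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tname, frame in tables.items():
            path = outdir / f"{name}_{tname}.csv"
            frame.to_csv(path, index=False)
            files[tname] = path.name
        spath = outdir / f"{name}_summary.json"
        with open(spath, "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        files["summary"] = spath.name
        for cname, comp in (comparisons or {}).items():
            ppath = outdir / f"{name}_{cname}.png"
            plot_comparison(comp, ppath)
            files[cname + "_png"] = ppath.name
    return files


# -- experiments ----------------------------------------------------------


def run_complexity_comparison(spec: ExperimentSpec, outdir=None) -> dict:
    """Heterogeneous vs homogeneous brain on one skull-stripped mesh."""
    full = build_layered_phantom(spec.phantom)
    brain = strip_skull(full)
    het = MaterialSet.complexity_heterogeneous()
    hom = MaterialSet.complexity_homogeneous()
    res_het, _ = _solve_scenario(brain, het, "exterior", spec)
    res_hom, _ = _solve_scenario(brain, hom, "exterior", spec)
    comp = compare(res_het, res_hom, threshold=spec.pairing_threshold,
                   labels=("heterogeneous", "homogeneous"))
    n = spec.n_modes
    summary = {
        "n_modes": n,
        "threshold": spec.pairing_threshold,
        "n_paired": comp.n_paired,
        "n_unique_heterogeneous": len(comp.unpaired_a),
        "n_unique_homogeneous": len(comp.unpaired_b),
        "bookkeeping_heterogeneous": comp.n_paired + len(comp.unpaired_a),
        "bookkeeping_homogeneous": comp.n_paired + len(comp.unpaired_b),
    }
    tables = {
        "frequencies": pd.DataFrame({
            "mode": np.arange(1, n + 1),
            "f_heterogeneous_hz": res_het.frequencies_hz,
            "f_homogeneous_hz": res_hom.frequencies_hz,
        }),
        "pairs": comp.to_frame(),
    }
    files = _write_report(outdir, "complexity", tables, summary,
                          {"comparison": comp})
    return {"tables": tables, "summary": summary, "comparison": comp,
            "results": {"heterogeneous": res_het, "homogeneous": res_hom},
            "files": files}


_BC_NAMES = ("skull", "neck", "spine", "fmri", "noskull")


def run_bc_comparison(spec: ExperimentSpec, outdir=None) -> dict:
    """Five boundary-condition scenarios on one phantom family."""
    base_mesh = build_layered_phantom(spec.phantom)
    if "SKULL" not in base_mesh.regions:
        raise ValueError("bc comparison requires a 4-shell phantom")
    mats = MaterialSet.tse_reference()
    radius = spec.phantom.appendage_radius

    meshes = {
        "skull": base_mesh,
        "neck": attach_cylinder(base_mesh, 120.0, radius, "NECK"),
        "spine": attach_cylinder(base_mesh, 500.0, radius, "SPINE"),
        "fmri": base_mesh,
        "noskull": strip_skull(base_mesh),
    }
    fixes = {
        "skull": "base",
        "neck": "cylinder_base",
        "spine": "cylinder_base",
        "fmri": "base_back_sides",
        "noskull": "exterior",
    }
    results = {}
    for name in _BC_NAMES:
        results[name], _ = _solve_scenario(meshes[name], mats, fixes[name], spec)

    freq = pd.DataFrame(
        {"mode": np.arange(1, spec.n_modes + 1)}
        | {f"f_{n}_hz": results[n].frequencies_hz for n in _BC_NAMES})

    comparisons = {}
    for i, a in enumerate(_BC_NAMES):
        for b in _BC_NAMES[i + 1:]:
            comparisons[f"{a}_vs_{b}"] = _cross_mesh_compare(
                meshes[a], results[a], meshes[b], results[b],
                spec.pairing_threshold, (a, b))

    f1 = {n: float(results[n].frequencies_hz[0]) for n in _BC_NAMES}
    nf = comparisons["fmri_vs_noskull"]
    entries = []
    for name in _BC_NAMES:
        sa, _ = _restricted_shapes(
            meshes[name], results[name], meshes["skull"], results["skull"])
        entries.append((name, sa))
    # shape classes counted on shared brain DOFs with the disclosed threshold
    n_distinct = _count_distinct_shapes(entries, spec.pairing_threshold)

    summary = {
        "fundamental_hz": f1,
        "fundamental_trend_skull_gt_neck_gt_spine":
            bool(f1["skull"] > f1["neck"] > f1["spine"]),
        "fmri_vs_noskull_nrfd_max": float(nf.nrfd.max()) if nf.nrfd.size else None,
        "fmri_vs_noskull_nrfd_mean": float(nf.nrfd.mean()) if nf.nrfd.size else None,
        "n_distinct_mode_shapes": n_distinct,
        "distinct_shape_threshold": spec.pairing_threshold,
        "n_converged": {n: results[n].n_converged for n in _BC_NAMES},
    }
    tables = {"frequencies": freq}
    for cname, comp in comparisons.items():
        tables[f"pairs_{cname}"] = comp.to_frame()
    files = _write_report(outdir, "bc", tables, summary, comparisons)
    return {"tables": tables, "summary": summary, "comparisons": comparisons,
            "results": results, "meshes": meshes, "files": files}


def run_csf_sweep(spec: ExperimentSpec, brain: str = "high",
                  grid=CSF_E_GRID, outdir=None) -> dict:
    """CSF Young's modulus sweep vs the stiffest (reference) value."""
    if brain not in BRAIN_STIFFNESS:
        raise ValueError(f"brain must be one of {sorted(BRAIN_STIFFNESS)}")
    grid = tuple(grid)
    mesh = build_layered_phantom(spec.phantom)
    results = {}
    for e_csf in grid:
        mats = MaterialSet.csf_sweep(e_csf, brain=brain)
        results[e_csf], _ = _solve_scenario(mesh, mats, "base", spec)

    ref_e = grid[0]
    ref = results[ref_e]
    comparisons = {}
    for e_csf in grid:
        comp = compare(ref, results[e_csf], threshold=spec.pairing_threshold,
                       labels=(f"CSF {ref_e} MPa", f"CSF {e_csf} MPa"))
        comparisons[f"E_{e_csf:g}"] = comp

    freq = pd.DataFrame(
        {"mode": np.arange(1, spec.n_modes + 1)}
        | {f"f_csf_{e:g}_hz": results[e].frequencies_hz for e in grid})

    freqs = np.column_stack([results[e].frequencies_hz for e in grid])
    monotone = bool((np.diff(freqs, axis=1) <= 1e-9 * freqs[:, :1]).all())
    fundamental_nrfd = [
        nrfd(ref.frequencies_hz[0], results[e].frequencies_hz[0]) for e in grid]
    nrfd_monotone = bool((np.diff(fundamental_nrfd) >= -1e-12).all())

    mac_vs_mode = []
    for e in grid[1:]:
        comp = comparisons[f"E_{e:g}"]
        for i, _k, m in comp.pairing:
            mac_vs_mode.append(
                {"E_csf_MPa": e, "mode": i + 1, "mac": m,
                 "f_ref_hz": float(ref.frequencies_hz[i])})
    mac_trend = pd.DataFrame(mac_vs_mode)

    summary = {
        "brain_scenario": brain,
        "E_grid_MPa": list(grid),
        "reference_E_MPa": ref_e,
        "frequencies_nonincreasing_with_softer_csf": monotone,
        "fundamental_nrfd_vs_reference": fundamental_nrfd,
        "fundamental_nrfd_nondecreasing": nrfd_monotone,
        "min_frequency_hz": float(freqs.min()),
    }
    tables = {"frequencies": freq, "mac_by_mode": mac_trend}
    for cname, comp in comparisons.items():
        tables[f"pairs_{cname}"] = comp.to_frame()
    files = _write_report(outdir, f"csf_sweep_{brain}", tables, summary,
                          comparisons)
    return {"tables": tables, "summary": summary, "comparisons": comparisons,
            "results": results, "files": files}


def run_ratio_hypothesis(spec: ExperimentSpec, c: float = 2.0,
                         outdir=None) -> dict:
    """Stiffness-ratio hypothesis: exact global-scaling law + mixed pairs."""
    mesh = build_layered_phantom(spec.phantom)

    # exact law: all region E scaled by one constant c
    base = MaterialSet.csf_sweep(0.012, brain="high")
    scaled = base.scaled(c)
    res_base, _ = _solve_scenario(mesh, base, "base", spec)
    res_scaled, _ = _solve_scenario(mesh, scaled, "base", spec)
    comp_exact = compare(res_base, res_scaled,
                         threshold=spec.pairing_threshold,
                         labels=("base", f"all E x {c:g}"))
    diag_mac = np.array([m for _i, _k, m in comp_exact.pairing])
    ratio = res_scaled.frequencies_hz / res_base.frequencies_hz
    exact = {
        "c": c,
        "expected_frequency_ratio": float(np.sqrt(c)),
        "max_abs_ratio_error": float(np.abs(ratio - np.sqrt(c)).max()),
        "min_pair_mac": float(diag_mac.min()) if diag_mac.size else None,
        "all_modes_paired": comp_exact.n_paired == spec.n_modes,
    }

    # mixed pairs: approximately equal brain/CSF stiffness ratios
    mixed_specs = {
        "high12kPa_vs_low1kPa": (("high", 0.012), ("low", 0.001)),
        "high1kPa_vs_low0.1kPa": (("high", 0.001), ("low", 0.0001)),
    }
    mixed = {}
    comparisons = {"exact_scaling": comp_exact}
    for name, ((br_a, e_a), (br_b, e_b)) in mixed_specs.items():
        ra, _ = _solve_scenario(
            mesh, MaterialSet.csf_sweep(e_a, brain=br_a), "base", spec)
        rb, _ = _solve_scenario(
            mesh, MaterialSet.csf_sweep(e_b, brain=br_b), "base", spec)
        comp = compare(ra, rb, threshold=0.0, labels=name.split("_vs_"))
        macs = np.array([m for _i, _k, m in comp.pairing])
        mixed[name] = {
            "n_mac_above_0.8": int((macs > 0.8).sum()),
            "n_mac_0.5_to_0.8": int(((macs >= 0.5) & (macs <= 0.8)).sum()),
            "n_mac_below_0.5": int((macs < 0.5).sum()),
            "min_frequency_a_hz": float(ra.frequencies_hz[0]),
            "min_frequency_b_hz": float(rb.frequencies_hz[0]),
        }
        comparisons[name] = comp

    summary = {"exact_scaling": exact, "mixed_pairs": mixed}
    tables = {"exact_pairs": comp_exact.to_frame()}
    for cname in mixed_specs:
        tables[f"pairs_{cname}"] = comparisons[cname].to_frame()
    files = _write_report(outdir, "ratio", tables, summary, comparisons)
    return {"tables": tables, "summary": summary, "comparisons": comparisons,
            "files": files}


def run_all(spec: ExperimentSpec, outdir=None) -> dict:
    """Run every experiment; return (and optionally write) a manifest."""
    t0 = time.time()
    stages = {
        "complexity": lambda: run_complexity_comparison(spec, outdir),
        "bc": lambda: run_bc_comparison(spec, outdir),
        "csf_sweep_high": lambda: run_csf_sweep(spec, "high", outdir=outdir),
        "csf_sweep_low": lambda: run_csf_sweep(spec, "low", outdir=outdir),
        "ratio": lambda: run_ratio_hypothesis(spec, outdir=outdir),
    }
    reports, failures = {}, {}
    for name, fn in stages.items():
        try:
            reports[name] = fn()
        except Exception as exc:  # record and continue; manifest marks it
            failures[name] = f"{type(exc).__name__}: {exc}"

    import scipy
    manifest = {
        "config_hash": spec.config_hash(),
        "seed": spec.seed,
        "versions": {
            "brainmodes": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "experiments": {
            name: {"status": "ok", "summary": reports[name]["summary"],
                   "files": reports[name].get("files", {})}
            for name in reports
        } | {
            name: {"status": "failed", "error": err}
            for name, err in failures.items()
        },
        "complete": not failures,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t0, 2),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return {"manifest": manifest, "reports": reports}
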