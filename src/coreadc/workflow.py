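"""End-to-end K-edge calculation pipeline and error statistics.

``run_calculation`` executes the full workflow for one molecule and one
K-edge: SCF reference -> CVS partition -> DF tensor -> (reduced mode only:
global NAF truncation) -> CVS-CIS for all states -> per-state loop
(reduced mode: state-averaged density -> VNOs -> second NAF truncation)
-> CVS-ADC(2) -> oscillator strength.  Canonical mode skips every
compression step; both modes emit the identical table schema so error
statistics are a diff of two runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import adc2, cis, compression, properties
from .constants import HARTREE_TO_EV
from .df import build_df_tensor
from .molecule import FIXTURES, Molecule, fixture, load_xyz
from .reference import OrbitalSpace, ScfReference, compute_reference, \
    partition_orbitals


class WorkflowError(RuntimeError):
    pass


@dataclass
class RunConfig:
    geometry: str = "h2o"             # fixture name or XYZ path
    basis: str = "6-31g"
    aux_basis: str = "auto"
    cvs: str = "O 1s"
    n_states: int = 3
    eps_naf: float = compression.DEFAULT_EPS_NAF
    eps_vno: float = compression.DEFAULT_EPS_VNO
    mode: str = "reduced"
    frozen_policy: str = "freeze-other-cores"
    energy_tolerance: float = 1.0e-6
    residual_tolerance: float = 1.0e-5
    cache_dir: str | None = None      # on-disk DF-integral cache
    seed: int = 0                     # randomized test utilities only

    def __post_init__(self):
        if self.mode not in ("canonical", "reduced"):
            raise WorkflowError(f"mode must be canonical|reduced, "
                                f"got {self.mode!r}")
        if self.eps_naf < 0 or self.eps_vno < 0:
            raise WorkflowError("truncation thresholds must be >= 0")


@dataclass
class ResultsTable:
    """Per-state results; columns mirror the reporting layout
    (energy in eV, f, retained VNO %, retained NAF %)."""

    molecule: str
    basis: str
    cvs: str
    mode: str
    rows: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_text(self) -> str:
        head = (f"# {self.molecule}  {self.cvs} K-edge  basis={self.basis}"
                f"  mode={self.mode}\n")
        head += (f"{'state':>5s} {'omega/eV':>10s} {'f':>8s} "
                 f"{'VNO%':>7s} {'NAF%':>7s} {'conv':>5s}\n")
        lines = []
        for row in self.rows:
            lines.append(
                f"{row['state']:>5d} {row['omega_ev']:>10.2f} "
                f"{row['f']:>8.4f} {row['retained_vno_pct']:>7.1f} "
                f"{row['retained_naf_pct']:>7.1f} "
                f"{'yes' if row['converged'] else 'NO':>5s}")
        return head + "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=float)

    @classmethod
    def from_json(cls, text: str) -> "ResultsTable":
        data = json.loads(text)
        return cls(**data)

    def write(self, path, fmt: str = "json") -> None:
        if not self.rows:
            raise WorkflowError("refusing to write an empty results table")
        with open(path, "w") as fh:
            fh.write(self.to_json() if fmt == "json" else self.to_text())


def load_geometry(name_or_path: str) -> Molecule:
    """Fixture name or XYZ file path -> Molecule."""
    if name_or_path.lower() in FIXTURES:
        return fixture(name_or_path)
    return load_xyz(name_or_path)


def _dipole_blocks(ref: ScfReference, space: OrbitalSpace,
                   vno_rotation: np.ndarray | None = None):
    """MO dipole blocks (combined correlated occupied, current virtuals)."""
    mu_ao = ref.ao_dipole()
    c = ref.mo_coefficients
    occ_idx = list(space.active_core) + list(space.inactive_occupied)
    c_occ = c[:, occ_idx]
    c_vir = c[:, list(space.virtual)]
    if vno_rotation is not None:
        c_vir = c_vir @ vno_rotation
    mu_ov = np.einsum("xmn,mk,na->xka", mu_ao, c_occ, c_vir, optimize=True)
    mu_oo = np.einsum("xmn,mk,nl->xkl", mu_ao, c_occ, c_occ, optimize=True)
    mu_vv = np.einsum("xmn,ma,nb->xab", mu_ao, c_vir, c_vir, optimize=True)
    return mu_ov, mu_oo, mu_vv


def run_calculation(config: RunConfig,
                    reference: ScfReference | None = None) -> ResultsTable:
    """Execute the workflow; ``reference`` may be supplied to share one SCF
    between several edges of the same molecule."""
    t_start = time.time()
    stage = "reference"
    try:
        mol = load_geometry(config.geometry)
        ref = reference or compute_reference(mol, config.basis,
                                             config.aux_basis,
                                             cache_dir=config.cache_dir)
        stage = "cvs-partition"
        space = partition_orbitals(ref, config.cvs, config.frozen_policy)
        stage = "df-tensor"
        j0 = build_df_tensor(ref, space)
        n_aux_total = j0.n_aux

        stage = "naf-global"
        if config.mode == "reduced" and config.eps_naf > 0:
            naf1 = compression.build_naf(j0, config.eps_naf)
            j1 = j0.rotate_auxiliary(naf1.rotation)
        else:
            naf1 = None
            j1 = j0

        stage = "cvs-cis"
        guesses = cis.solve_cis(config.n_states, j1, space)

        settings = adc2.SolverSettings(
            n_states=1, energy_tolerance=config.energy_tolerance,
            residual_tolerance=config.residual_tolerance)

        mp2_canon = None
        table = ResultsTable(mol.name or config.geometry, config.basis,
                             config.cvs, config.mode)
        for istate, (omega_cis, rvec) in enumerate(guesses):
            stage = f"state {istate}"
            if config.mode == "reduced":
                sm = compression.reduce_state(
                    j1, (omega_cis, rvec), space,
                    eps_naf=config.eps_naf, eps_vno=config.eps_vno,
                    naf_total_aux=n_aux_total)
                jst, spst = sm.reduced_j, sm.reduced_space
                r0 = sm.project_singles(rvec.amplitudes)
                nr = np.linalg.norm(r0)
                if nr < 0.1:
                    raise WorkflowError(
                        f"state {istate}: CIS guess almost vanishes in the "
                        f"truncated VNO space (norm {nr:.3f}); loosen "
                        "eps_vno")
                guess = (omega_cis, cis.SinglesVector(r0 / nr))
                mp2st = adc2.mp2_intermediates(jst, spst)
                vno_pct = 100.0 * sm.retained_vno_fraction
                naf_pct = 100.0 * sm.retained_naf_fraction
                mu_ov, mu_oo, mu_vv = _dipole_blocks(ref, space,
                                                     sm.vno_rotation)
            else:
                jst, spst = j1, space
                guess = (omega_cis, rvec)
                if mp2_canon is None:
                    mp2_canon = adc2.mp2_intermediates(j1, space)
                mp2st = mp2_canon
                vno_pct = 100.0
                naf_pct = 100.0 * j1.n_aux / n_aux_total
                mu_ov, mu_oo, mu_vv = _dipole_blocks(ref, space)

            states = adc2.solve_adc2(settings, jst, spst, mp2st, [guess])
            st = states[0]
            tm = properties.transition_moment(st, jst, spst,
                                              mu_ov, mu_oo, mu_vv)
            st.oscillator_strength = tm.f
            table.rows.append({
                "state": istate + 1,
                "omega_ev": st.omega * HARTREE_TO_EV,
                "omega_hartree": st.omega,
                "f": tm.f,
                "retained_vno_pct": vno_pct,
                "retained_naf_pct": naf_pct,
                "converged": st.converged,
                "cis_overlap": st.diagnostics.get("cis_overlap"),
                "iterations": st.diagnostics.get("iterations"),
            })
        table.metadata = {
            "hf_energy": ref.hf_energy,
            "n_aux_total": n_aux_total,
            "n_virt": space.n_virt,
            "eps_naf": config.eps_naf,
            "eps_vno": config.eps_vno,
            "wall_seconds": time.time() - t_start,
        }
        return table
    except Exception as exc:
        if isinstance(exc, WorkflowError):
            raise
        raise WorkflowError(
            f"{config.geometry}/{config.cvs}: failure in stage "
            f"'{stage}': {exc}") from exc


# ---------------------------------------------------------------------------
# error statistics (canonical vs reduced)
# ---------------------------------------------------------------------------

def error_statistics(canonical: ResultsTable | list[ResultsTable],
                     reduced: ResultsTable | list[ResultsTable],
                     f_threshold: float = properties.F_STATISTICS_THRESHOLD,
                     exclude_degenerate: bool = False,
                     degeneracy_window_ev: float = 1.0e-3) -> dict:
    """MAE/MAX/SD on excitation energies and MRE/MAX on oscillator
    strengths (f > threshold, canonical reference), over one or several
    table pairs.

    ``exclude_degenerate`` drops one partner of each near-degenerate pair
    (canonical energies within the window)."""
    if isinstance(canonical, ResultsTable):
        canonical = [canonical]
    if isinstance(reduced, ResultsTable):
        reduced = [reduced]
    de, rf = [], []
    for ctab, rtab in zip(canonical, reduced):
        if len(ctab.rows) != len(rtab.rows):
            raise WorkflowError("table pair with differing state counts")
        keep = [True] * len(ctab.rows)
        if exclude_degenerate:
            for a in range(len(ctab.rows)):
                for b in range(a):
                    if keep[a] and keep[b] and abs(
                            ctab.rows[a]["omega_ev"]
                            - ctab.rows[b]["omega_ev"]) \
                            < degeneracy_window_ev:
                        keep[a] = False
        for k, (crow, rrow) in enumerate(zip(ctab.rows, rtab.rows)):
            if not keep[k]:
                continue
            de.append(rrow["omega_ev"] - crow["omega_ev"])
            if crow["f"] > f_threshold:
                rf.append(abs(rrow["f"] - crow["f"]) / crow["f"])
    de = np.array(de)
    out = {
        "n_states": int(de.size),
        "mae_ev": float(np.mean(np.abs(de))) if de.size else float("nan"),
        "max_ev": float(np.max(np.abs(de))) if de.size else float("nan"),
        "mean_ev": float(np.mean(de)) if de.size else float("nan"),
        "sd_ev": float(np.std(de, ddof=1)) if de.size > 1 else 0.0,
        "n_f": len(rf),
        "mre_f": float(np.mean(rf)) if rf else float("nan"),
        "max_rel_f": float(np.max(rf)) if rf else float("nan"),
    }
    return out
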