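"""Config-driven end-to-end runs and generated test fixtures.

Scenarios wire the simulator to the analysis chain (simulate -> measure ->
profile -> fit) with explicit seeds so a rerun with the same config is
bit-identical.  Fixture builders construct the toy structures used to
exercise the geometric and docking machinery: a four-chain poly-alanine
tetramer with engineered sites at configurable separations, and a two-body
"burial" system with a single analytic SG-occlusion optimum.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import profiles, simephys, traces
from .linkers import CATALOG, get_linker
from .structgeo import (ResidueSelector, Structure, VDW_RADII, mutate_to_cys,
                        write_structure)

# Ideal alanine heavy-atom template (local frame, A).
_ALA_TEMPLATE = {
    "N": np.array([-0.525, 1.363, 0.000]),
    "CA": np.array([0.000, 0.000, 0.000]),
    "C": np.array([1.526, 0.000, 0.000]),
    "O": np.array([2.153, 1.047, 0.000]),
    "CB": np.array([-0.507, -0.785, -1.206]),
}
_ALA_ORDER = ("N", "CA", "C", "O", "CB")


def _chain_arrays(chain_id: str, residue_numbers: Sequence[int],
                  origin: np.ndarray, rotation: np.ndarray | None = None):
    """A straight poly-alanine chain: one template residue per number,
    CA positions spaced 3.8 A along +y, centred on the chain midpoint so a
    180-degree flip about z maps the footprint onto itself."""
    R = np.eye(3) if rotation is None else rotation
    mid = (len(residue_numbers) - 1) / 2.0
    el, nm, rn, rname, ch, xyz = [], [], [], [], [], []
    for k, num in enumerate(residue_numbers):
        offset = origin + R @ np.array([0.0, 3.8 * (k - mid), 0.0])
        for name in _ALA_ORDER:
            el.append(name[0])
            nm.append(name)
            rn.append(num)
            rname.append("ALA")
            ch.append(chain_id)
            xyz.append(R @ _ALA_TEMPLATE[name] + offset)
    return el, nm, rn, rname, ch, xyz


def _build(parts) -> Structure:
    el, nm, rn, rname, ch, xyz = [], [], [], [], [], []
    for p in parts:
        el += p[0]; nm += p[1]; rn += p[2]; rname += p[3]; ch += p[4]
        xyz += p[5]
    vdw = np.array([VDW_RADII.get(e, 1.70) for e in el])
    return Structure(np.array(el), np.array(nm), np.array(rn, dtype=int),
                     np.array(rname), np.array(ch),
                     np.array(xyz, dtype=float), vdw)


def make_toy_tetramer(separation: float = 15.0, site: int = 666,
                      residue_numbers: Sequence[int] = (662, 664, 665, 666, 668),
                      ) -> Structure:
    """Four-chain poly-alanine arrangement with labelled engineered sites.

    Chains A and C are the proximal pair facing each other across the
    inter-dimer interface; after ``mutate_to_cys`` at ``site`` in both, the
    SG-SG distance equals ``separation`` exactly.  B and D are distal.
    """
    if site not in residue_numbers:
        raise ValueError(f"site {site} not among residue numbers")
    # chain A, shifted in x/z so its mutated-site SG lands on the y-axis;
    # the y-shift is left alone so that the flipped partner chain keeps the
    # dimer centroids symmetric about y = 0
    partsA = _chain_arrays("A", residue_numbers, np.zeros(3))
    stA = _build([partsA])
    stA.subunit_roles = {"A": "proximal_AC"}
    mutA = mutate_to_cys(stA, ResidueSelector("A", site))
    sg = mutA.coords[mutA.atom_index(ResidueSelector("A", site), "SG")]
    shift = np.array([-sg[0], 0.0, -sg[2]])
    sg_y = sg[1]
    if separation <= 2.0 * abs(sg_y):
        raise ValueError(f"separation {separation} too small for the toy "
                         f"template (needs > {2 * abs(sg_y):.2f} A)")
    # the flip mirrors the SG y-offset; solve the x-offset so that the
    # SG-SG distance equals the requested separation exactly
    dx = float(np.sqrt(separation**2 - (2.0 * sg_y) ** 2))

    flip = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z
    parts = [
        _chain_arrays("A", residue_numbers, shift),
        _chain_arrays("B", residue_numbers, shift + np.array([0.0, 22.0, 0.0])),
        _chain_arrays("C", residue_numbers,
                      flip @ shift + np.array([dx, 0.0, 0.0]), flip),
        _chain_arrays("D", residue_numbers,
                      flip @ shift + np.array([dx, 22.0, 0.0]), flip),
    ]
    st = _build(parts)
    st.subunit_roles = {"A": "proximal_AC", "B": "distal_BD",
                        "C": "proximal_AC", "D": "distal_BD"}
    st.title = f"toy tetramer, site {site} separation {separation:g} A"
    return st


def make_burial_toy(gap: float = 10.0, shell_radius: float = 4.5,
                    n_shell: int = 150, opening_deg: float = 50.0,
                    site: int = 666) -> tuple[Structure, Structure]:
    """Two rigid bodies with one analytic SG-burial optimum.

    The fixed body (chain A) is a single modelled cysteine whose SG points
    along +x at the origin.  The mobile body (chain C) carries an open
    spherical cage of carbon atoms centred ``gap`` A away along +x (opening
    towards the fixed side) plus its own cysteine.  Translating the mobile
    body by dx = -``gap`` places the SG at the cage centre, where it is
    fully occluded; the objective is minimal there and increases
    monotonically along the translation axis on either side.
    """
    from .structgeo import fibonacci_sphere, place_internal, SG_BOND, SG_ANGLE

    # fixed cysteine: backbone along -x so the SG is the +x-most atom
    n_ = np.array([-4.2, 0.8, 0.0])
    ca = np.array([-3.0, 0.0, 0.0])
    cb = np.array([-1.6, 0.4, 0.0])
    sg = place_internal(n_, ca, cb, SG_BOND, SG_ANGLE, 180.0)
    shift = -sg  # SG exactly at origin
    fixed_atoms = (["N", "C", "C", "S"], ["N", "CA", "CB", "SG"],
                   [site] * 4, ["CYS"] * 4, ["A"] * 4,
                   [n_ + shift, ca + shift, cb + shift, np.zeros(3)])
    fixed = _build([fixed_atoms])
    fixed.subunit_roles = {"A": "proximal_AC"}
    fixed.title = "burial toy, fixed"

    center = np.array([gap, 0.0, 0.0])
    pts = fibonacci_sphere(n_shell)
    keep = pts[:, 0] > -np.cos(np.deg2rad(opening_deg))  # open towards -x
    shell = center + shell_radius * pts[keep]
    ns = len(shell)
    cys_origin = center + np.array([shell_radius + 3.5, 0.0, 0.0])
    mob_cys = (["N", "C", "C", "S"], ["N", "CA", "CB", "SG"],
               [site] * 4, ["CYS"] * 4, ["C"] * 4,
               [cys_origin + np.array([3.0, 0.8, 0.0]),
                cys_origin + np.array([1.8, 0.0, 0.0]),
                cys_origin + np.array([0.9, 0.9, 0.0]),
                cys_origin])
    mob_shell = (["C"] * ns, [f"C{i+1}" for i in range(ns)],
                 [900] * ns, ["SHL"] * ns, ["C"] * ns, list(shell))
    mobile = _build([mob_cys, mob_shell])
    mobile.subunit_roles = {"C": "proximal_AC"}
    mobile.title = "burial toy, mobile cage"
    return fixed, mobile


def make_source_data_template() -> pd.DataFrame:
    """CSV skeleton matching the trapping-profile source-data layout."""
    rows = [{"linker": lk.name, "span_angstrom": lk.span, "mean": np.nan,
             "sem": np.nan, "n": 0} for lk in CATALOG.bifunctional()
            if lk.name != "disulfide"]
    return pd.DataFrame(rows)


def make_fixtures(kind: str, out_dir: str | Path, seed: int = 0,
                  **params) -> list[Path]:
    """Write a named fixture set to ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "toy_tetramer_pdb":
        st = make_toy_tetramer(**params)
        path = out / "toy_tetramer.pdb"
        path.write_text(write_structure(st))
        written.append(path)
    elif kind == "burial_toy":
        fixed, mobile = make_burial_toy(**params)
        for name, st in (("burial_fixed.pdb", fixed),
                         ("burial_mobile.pdb", mobile)):
            path = out / name
            path.write_text(write_structure(st))
            written.append(path)
    elif kind == "source_data_template":
        path = out / "source_data_template.csv"
        make_source_data_template().to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written


# -- scenarios -------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end scenario run."""

    scenario: str
    linkers: list
    conc: float = 1e-6
    protocol_kind: str = "trap_1min"
    n_patches: int = 4
    seed: int | None = None
    noise_sd: float = 2.0
    sample_rate: float = 20000.0
    out_dir: str = "runs"
    gating: dict = field(default_factory=dict)
    modification: dict = field(default_factory=dict)
    protocol_params: dict = field(default_factory=dict)

    _SCENARIOS = ("fig2_like", "fig3_like")

    def validate(self) -> None:
        if self.scenario not in self._SCENARIOS:
            raise ValueError(f"scenario: must be one of {self._SCENARIOS}")
        if not self.linkers:
            raise ValueError("linkers: at least one required")
        for name in self.linkers:
            get_linker(name)  # raises UnknownLinkerError
        if self.seed is None:
            raise ValueError("seed: an explicit seed is required")
        if self.n_patches < 1:
            raise ValueError("n_patches: must be >= 1")
        if self.conc <= 0:
            raise ValueError("conc: must be positive (molar)")

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _measure_trapping(trs, protocol, n_pre):
    pre, post = [], []
    for i, tr in enumerate(trs):
        sol_segments = protocol.episodes[i].bounds()
        if not any(s.agonist for _, _, s in sol_segments):
            continue
        if protocol.episodes[i].duration > 5.0:  # the trap episode
            continue
        win = protocol.response_window(i)
        base = protocol.baseline_window(i)
        val = traces.measure_episode(tr, win, base, "peak")
        (pre if len(pre) < n_pre else post).append(val)
    return pre, post


def run_scenario(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a scenario; writes per-patch CSV, fit JSON, and a run log.

    Returns a report dict with the output paths and headline numbers.
    """
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gating = simephys.GatingModel(**config.gating)
    mod = simephys.ModificationModel(**config.modification)
    rng = np.random.default_rng(config.seed)

    report: dict = {"scenario": config.scenario, "seed": config.seed}
    rows = []
    if config.scenario == "fig2_like":
        for name in config.linkers:
            linker = get_linker(name)
            for patch in range(config.n_patches):
                protocol = simephys.build_protocol(
                    config.protocol_kind, conc=config.conc,
                    sample_rate=config.sample_rate, **config.protocol_params)
                patch_seed = int(rng.integers(2**31 - 1))
                trs = simephys.simulate(gating, mod, protocol, linker,
                                        noise_sd=config.noise_sd,
                                        seed=patch_seed)
                pre, post = _measure_trapping(trs, protocol, n_pre=4)
                m = traces.active_fraction(pre, post)
                rows.append({"patch_id": f"{name}_{patch}", "linker": name,
                             "condition": config.scenario,
                             "active_fraction": m.active_fraction,
                             "seed": patch_seed})
        df = pd.DataFrame(rows)
        per_linker = {name: df[df.linker == name].active_fraction.tolist()
                      for name in config.linkers}
        points = profiles.build_profile(per_linker)
        fit = profiles.fit_parabola(points)
        profile_csv = out / "profile.csv"
        profiles.profile_frame(points).to_csv(profile_csv, index=False)
        fit_json = out / "parabola_fit.json"
        fit_json.write_text(json.dumps(profiles.fit_report(fit), indent=1))
        report.update({"profile_csv": str(profile_csv),
                       "fit_json": str(fit_json),
                       "K2": fit.K2, "K0": fit.K0})
    else:  # fig3_like: 50 uM pulse train, fitted trapping tau per linker
        taus = {}
        for name in config.linkers:
            linker = get_linker(name)
            protocol = simephys.build_protocol(
                "pulse_train_6p7Hz", conc=config.conc,
                sample_rate=config.sample_rate, **config.protocol_params)
            trs = simephys.simulate(gating, mod, protocol, linker,
                                    noise_sd=config.noise_sd,
                                    seed=int(rng.integers(2**31 - 1)))
            peaks, exposure = [], []
            t_exp = 0.0
            for i, tr in enumerate(trs):
                win = protocol.response_window(i)
                peaks.append(traces.measure_episode(tr, win, None, "peak"))
                exposure.append(t_exp)
                t_exp += win[1] - win[0]
            # tau is fitted against cumulative exposure time from the second
            # pulse on: the first pulse starts from a fully recovered
            # population, so its gating envelope differs from the rest of
            # the train (the same reason the active-fraction statistic skips
            # the first post-trap response)
            x = np.array(exposure[1:]) - exposure[1]
            y = np.array(peaks[1:]) / peaks[1]
            fit = traces.fit_exponential(x, y, 1)
            taus[name] = fit.taus[0]
            rows.append({"linker": name, "tau_s": fit.taus[0],
                         "weighted_tau_s": fit.weighted_tau})
        df = pd.DataFrame(rows)
        report["taus"] = taus
    patch_csv = out / "per_patch.csv"
    df.to_csv(patch_csv, index=False)
    report["per_patch_csv"] = str(patch_csv)

    digest = hashlib.sha256(
        df.to_csv(index=False).encode()).hexdigest()[:16]
    log = out / "run_log.txt"
    from . import __version__
    log.write_text(f"scenario={config.scenario}\nseed={config.seed}\n"
                   f"version={__version__}\noutput_sha256={digest}\n")
    report["log"] = str(log)
    report["output_digest"] = digest
    return report
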