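"""Reduced systemic arterial tree: generic definition and per-subject adjustment.

The tree is a rooted collection of elastic segments (geometry + distensibility)
closed by three-element Windkessel terminals.  A generic reference tree is
shipped as a versioned JSON table; per-subject adaptation scales segment
lengths with height, lumen areas with body surface area, and proximal aortic
distensibility with an age-graded stiffening factor.  Global compliance /
resistance / inflow-peak scaling factors (s_C, s_R, s_Q) are the three free
parameters of the inverse stroke-volume estimator.

All quantities here are in clinical units: cm, cm², mmHg, mL, mmHg·s/mL.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError
from .units import dubois_bsa, MMHG_TO_PA

__all__ = [
    "ArterialSegment",
    "WindkesselTerminal",
    "ArterialTree",
    "ScalingFactors",
    "SubjectRecord",
    "build_generic_tree",
    "adjust_anatomy",
    "apply_age_distensibility",
    "apply_scalings",
]

SCALING_BOUNDS = (0.2, 5.0)


@dataclass
class ArterialSegment:
    """One elastic 1-D segment with linear area taper."""

    name: str
    length_cm: float
    area_prox_cm2: float
    area_dist_cm2: float
    distensibility_per_mmhg: float
    is_terminal: bool = False

    def validate(self) -> None:
        if self.length_cm <= 0:
            raise ValidationError(f"segment {self.name}: length must be > 0")
        if self.area_prox_cm2 <= 0 or self.area_dist_cm2 <= 0:
            raise ValidationError(f"segment {self.name}: areas must be > 0")
        if self.distensibility_per_mmhg <= 0:
            raise ValidationError(f"segment {self.name}: distensibility must be > 0")

    @property
    def volume_ml(self) -> float:
        # linear area taper integrates to the mean-area volume
        return self.length_cm * 0.5 * (self.area_prox_cm2 + self.area_dist_cm2)

    @property
    def compliance_ml_mmhg(self) -> float:
        return self.distensibility_per_mmhg * self.volume_ml

    def wave_speed_mps(self, blood_density_kg_m3: float) -> float:
        """Bramwell–Hill wave speed 1/sqrt(rho*D) at the reference pressure."""
        d_pa = self.distensibility_per_mmhg / MMHG_TO_PA
        return 1.0 / np.sqrt(blood_density_kg_m3 * d_pa)


@dataclass
class WindkesselTerminal:
    """Three-element Windkessel outflow model closing a terminal segment."""

    segment_name: str
    r_char_mmhg_s_ml: float
    r_periph_mmhg_s_ml: float
    c_term_ml_mmhg: float

    def validate(self) -> None:
        if min(self.r_char_mmhg_s_ml, self.r_periph_mmhg_s_ml,
               self.c_term_ml_mmhg) <= 0:
            raise ValidationError(
                f"terminal {self.segment_name}: Windkessel values must be > 0")

    @property
    def r_total_mmhg_s_ml(self) -> float:
        return self.r_char_mmhg_s_ml + self.r_periph_mmhg_s_ml


@dataclass(frozen=True)
class ScalingFactors:
    """Global multipliers for compliance, peripheral resistance and inflow peak."""

    s_c: float = 1.0
    s_r: float = 1.0
    s_q: float = 1.0
    bounds: tuple[float, float] = SCALING_BOUNDS

    def __post_init__(self):
        lo, hi = self.bounds
        for label, v in (("s_c", self.s_c), ("s_r", self.s_r), ("s_q", self.s_q)):
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"scaling {label}={v:g} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_c, self.s_r, self.s_q])


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and non-invasive measurements for one person."""

    id: str
    gender: str
    age: float
    height_cm: float
    weight_kg: float
    brsbp_mmhg: float
    brdbp_mmhg: float
    hr_bpm: float
    cfpwv_mps: float
    sv_ref_ml: Optional[float] = None

    def __post_init__(self):
        if self.gender not in ("M", "F"):
            raise ValidationError(f"subject {self.id}: gender must be M or F")
        if not (self.brsbp_mmhg > self.brdbp_mmhg > 0):
            raise ValidationError(
                f"subject {self.id}: require brSBP > brDBP > 0 "
                f"(got {self.brsbp_mmhg}/{self.brdbp_mmhg})")
        if not (20 <= self.hr_bpm <= 220):
            raise ValidationError(f"subject {self.id}: HR {self.hr_bpm} outside 20-220 bpm")
        if not (2 <= self.cfpwv_mps <= 25):
            raise ValidationError(f"subject {self.id}: cfPWV {self.cfpwv_mps} outside 2-25 m/s")
        if self.age < 18:
            raise ValidationError(f"subject {self.id}: age must be >= 18")
        if self.height_cm < 100:
            raise ValidationError(f"subject {self.id}: height {self.height_cm} cm non-physiological")

    @property
    def map_mmhg(self) -> float:
        """Conventional cuff estimate of mean arterial pressure, DBP + PP/3."""
        return self.brdbp_mmhg + (self.brsbp_mmhg - self.brdbp_mmhg) / 3.0


AORTIC_PREFIXES = ("ascending_aorta", "aortic_arch", "thoracic_aorta",
                   "abdominal_aorta")


@dataclass
class ArterialTree:
    """A validated rooted arterial tree with Windkessel terminals."""

    segments: list[ArterialSegment]
    parent_of: dict[str, Optional[str]]
    terminals: dict[str, WindkesselTerminal]
    sites: dict[str, tuple[str, float]]      # site -> (segment name, fraction 0-1)
    blood_density_kg_m3: float = 1060.0
    blood_viscosity_mpa_s: float = 4.0
    reference_pressure_mmhg: float = 100.0
    meta: dict = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    def segment(self, name: str) -> ArterialSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise ValidationError(f"unknown segment {name!r}")

    @property
    def root(self) -> str:
        roots = [n for n, p in self.parent_of.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots}")
        return roots[0]

    def children_of(self, name: str) -> list[str]:
        return [s.name for s in self.segments if self.parent_of.get(s.name) == name]

    def ancestors(self, name: str) -> list[str]:
        out, cur = [], self.parent_of.get(name)
        while cur is not None:
            out.append(cur)
            cur = self.parent_of.get(cur)
            if len(out) > len(self.segments):
                raise ValidationError(f"cyclic connectivity at segment {name!r}")
        return out

    def path_length_to_site(self, site: str) -> float:
        """Arc length (cm) from the root inlet to a named measurement site."""
        seg_name, frac = self.sites[site]
        seg = self.segment(seg_name)
        upstream = sum(self.segment(a).length_cm for a in self.ancestors(seg_name))
        return upstream + frac * seg.length_cm

    # -- aggregates --------------------------------------------------------
    def total_peripheral_resistance(self) -> float:
        return 1.0 / sum(1.0 / t.r_total_mmhg_s_ml for t in self.terminals.values())

    def total_compliance(self) -> float:
        seg_c = sum(s.compliance_ml_mmhg for s in self.segments)
        term_c = sum(t.c_term_ml_mmhg for t in self.terminals.values())
        return seg_c + term_c

    def theoretical_cfpwv(self) -> float:
        """Path-averaged carotid-femoral PWV from segment reference wave speeds.

        Transit times along the (root->femoral) and (root->carotid) paths are
        accumulated from segmental Bramwell-Hill speeds; the speed is the
        subtracted path length over the transit-time difference.  Used as a
        cheap predictor (optimizer warm start), not as the simulated cfPWV.
        """
        def path_time(site):
            seg_name, frac = self.sites[site]
            t = 0.0
            for a in self.ancestors(seg_name):
                s = self.segment(a)
                t += (s.length_cm / 100.0) / s.wave_speed_mps(self.blood_density_kg_m3)
            s = self.segment(seg_name)
            t += frac * (s.length_cm / 100.0) / s.wave_speed_mps(self.blood_density_kg_m3)
            return t

        dist = (self.path_length_to_site("femoral")
                - self.path_length_to_site("carotid")) / 100.0
        dt = path_time("femoral") - path_time("carotid")
        return dist / dt

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate segment names")
        for s in self.segments:
            s.validate()
            if s.name not in self.parent_of:
                raise ValidationError(f"segment {s.name}: missing connectivity entry")
            p = self.parent_of[s.name]
            if p is not None and p not in names:
                raise ValidationError(f"segment {s.name}: unknown parent {p!r}")
            if p == s.name:
                raise ValidationError(f"segment {s.name}: is its own parent")
        _ = self.root
        for s in self.segments:
            self.ancestors(s.name)  # raises on cycles
            if s.is_terminal and s.name not in self.terminals:
                raise ValidationError(f"terminal segment {s.name}: missing Windkessel terminal")
            if s.is_terminal and self.children_of(s.name):
                raise ValidationError(f"terminal segment {s.name}: has children")
            if not s.is_terminal and not self.children_of(s.name):
                raise ValidationError(f"segment {s.name}: no children and not terminal")
            if s.name.startswith(AORTIC_PREFIXES) and s.area_dist_cm2 > s.area_prox_cm2:
                raise ValidationError(f"aortic segment {s.name}: area must taper")
        for t in self.terminals.values():
            t.validate()
            if t.segment_name not in names:
                raise ValidationError(f"terminal references unknown segment {t.segment_name!r}")
        for site, (seg_name, frac) in self.sites.items():
            if seg_name not in names:
                raise ValidationError(f"site {site!r}: unresolvable segment {seg_name!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"site {site!r}: fraction must be in [0, 1]")

    def copy(self) -> "ArterialTree":
        return copy.deepcopy(self)


def _default_config() -> dict:
    with resources.files("pulsesv.data").joinpath("generic_tree.json").open() as f:
        return json.load(f)


def build_generic_tree(config: dict | str | Path | None = None) -> ArterialTree:
    """Build and validate the generic reference tree from a definition table.

    ``config`` may be None (packaged default), a path to a JSON file, or an
    already-parsed dict.  The declared reference total peripheral resistance
    and total compliance must match the table within 1e-6 relative.
    """
    if config is None:
        cfg = _default_config()
    elif isinstance(config, (str, Path)):
        with open(config) as f:
            cfg = json.load(f)
    else:
        cfg = config

    segs = [ArterialSegment(
        name=row["name"], length_cm=row["length_cm"],
        area_prox_cm2=row["area_prox_cm2"], area_dist_cm2=row["area_dist_cm2"],
        distensibility_per_mmhg=row["distensibility_per_mmhg"],
        is_terminal=bool(row["is_terminal"])) for row in cfg["segments"]]
    if len(segs) < 20:
        raise ValidationError(f"tree definition must list >= 20 segments, got {len(segs)}")
    parent_of = {row["name"]: row["parent"] for row in cfg["segments"]}
    terminals = {t["segment"]: WindkesselTerminal(
        segment_name=t["segment"], r_char_mmhg_s_ml=t["r_char_mmhg_s_ml"],
        r_periph_mmhg_s_ml=t["r_periph_mmhg_s_ml"],
        c_term_ml_mmhg=t["c_term_ml_mmhg"]) for t in cfg["terminals"]}
    sites = {k: (v["segment"], v["fraction"]) for k, v in cfg["sites"].items()}
    for required in ("carotid", "brachial", "femoral"):
        if required not in sites:
            raise ValidationError(f"missing measurement site {required!r}")

    tree = ArterialTree(
        segments=segs, parent_of=parent_of, terminals=terminals, sites=sites,
        blood_density_kg_m3=cfg.get("blood_density_kg_m3", 1060.0),
        blood_viscosity_mpa_s=cfg.get("blood_viscosity_mpa_s", 4.0),
        reference_pressure_mmhg=cfg.get("reference_pressure_mmhg", 100.0),
        meta={k: v for k, v in cfg.items() if k not in ("segments", "terminals", "sites")},
    )
    tree.validate()
    for key, actual in (("reference_r_total_mmhg_s_ml", tree.total_peripheral_resistance()),
                        ("reference_c_total_ml_mmhg", tree.total_compliance())):
        declared = cfg.get(key)
        if declared is not None and abs(actual - declared) > 1e-6 * abs(declared):
            raise ValidationError(
                f"{key}: declared {declared:g} but table gives {actual:g}")
    return tree


def adjust_anatomy(tree: ArterialTree, subject: SubjectRecord) -> ArterialTree:
    """Scale the generic geometry to a subject's body size.

    Segment lengths scale with height/H_ref; lumen areas with BSA/BSA_ref
    (DuBois).  Gender is geometry-neutral under the default configuration
    (a per-gender area offset hook exists in the tree definition file).
    """
    if subject.height_cm < 100:
        raise ValidationError(f"height {subject.height_cm} cm non-physiological")
    h_ref = tree.meta.get("reference_height_cm", 170.0)
    w_ref = tree.meta.get("reference_weight_kg", 70.0)
    len_scale = subject.height_cm / h_ref
    area_scale = (dubois_bsa(subject.height_cm, subject.weight_kg)
                  / dubois_bsa(h_ref, w_ref))
    area_offset = tree.meta.get("gender_area_offset", {}).get(subject.gender, 0.0)

    out = tree.copy()
    for s in out.segments:
        s.length_cm *= len_scale
        s.area_prox_cm2 = s.area_prox_cm2 * area_scale + area_offset
        s.area_dist_cm2 = s.area_dist_cm2 * area_scale + area_offset
    out.validate()
    return out


def _age_factor(age: float, ages, factors) -> float:
    return float(np.interp(age, ages, factors))


def apply_age_distensibility(tree: ArterialTree, age: float) -> ArterialTree:
    """Stiffen the aorta with age (non-uniform, strongest proximally).

    Proximal aortic distensibility (ascending + arch) is multiplied by a
    non-increasing factor g(age) with g(25) = 1; the remaining aortic trunk
    receives a milder decline so that the carotid-femoral transit time (whose
    path is dominated by the descending aorta) carries the age gradient.
    Non-aortic segments are unchanged.  Factor tables live in the tree
    definition file and are declared calibrations.
    """
    if age < 18:
        raise ValidationError(f"age {age} below adult range")
    aging = tree.meta.get("aging")
    if aging is None:
        return tree.copy()
    g_prox = _age_factor(age, aging["ages"], aging["proximal_factor"])
    g_dist = _age_factor(age, aging["ages"], aging["distal_aortic_factor"])
    out = tree.copy()
    for s in out.segments:
        if s.name in aging["proximal_segments"]:
            s.distensibility_per_mmhg *= g_prox
        elif s.name in aging["distal_aortic_segments"]:
            s.distensibility_per_mmhg *= g_dist
    return out


def apply_scalings(tree: ArterialTree, s: ScalingFactors) -> ArterialTree:
    """Apply global compliance and resistance scalings to a tree.

    s_C multiplies every segment distensibility and every terminal compliance;
    s_R multiplies both Windkessel resistances of every terminal (so the total
    peripheral resistance scales exactly by s_R).  s_Q is not applied here: it
    parameterizes the inflow wave.
    """
    out = tree.copy()
    for seg in out.segments:
        seg.distensibility_per_mmhg *= s.s_c
    for t in out.terminals.values():
        t.c_term_ml_mmhg *= s.s_c
        t.r_char_mmhg_s_ml *= s.s_r
        t.r_periph_mmhg_s_ml *= s.s_r
    return out


def subject_tree(subject: SubjectRecord,
                 config: dict | str | Path | None = None) -> ArterialTree:
    """Generic tree -> anatomy adjustment -> age-graded stiffening."""
    tree = build_generic_tree(config)
    tree = adjust_anatomy(tree, subject)
    return apply_age_distensibility(tree, subject.age)
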