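"""USEPA drinking-water health-risk indices for arsenic and their map classes.

Carcinogenic risk is the target risk (TR), the incremental lifetime cancer
probability from chronic ingestion:

    TR = (C * IR / BW) * (EF * ED / AT) * CSF * 1e-3

with C the arsenic concentration in ug/L and 1e-3 the ug->mg conversion for
the slope factor.  Non-carcinogenic risk is the hazard quotient

    DI = C * IR / BW        (daily intake, ug/kg/day)
    HQ = DI / RfD

HQ > 1 flags possible adverse non-cancer effects.  Default exposure
parameters are the local adult-resident values: 1.4 L/day intake, 64.5 kg
body weight, 365 day/yr frequency for 30 yr, averaged over a 79.0-year
lifetime (79.0 x 365 = 28,835 days), with the IRIS oral RfD of 0.3 ug/kg/day
and cancer slope factor 1.5 (mg/kg/day)^-1 for inorganic arsenic.

Classification conventions (boundaries resolved explicitly):
* TR level 1 (negligible) below 1e-6, level 2 (acceptable) for 1e-6..1e-4
  inclusive, level 3 (unacceptable) above 1e-4.
* HQ level 1 (adverse possible) strictly above 1, else level 2.
* Concentration classes are the half-open WHO-anchored bands
  [0,5), [5,10), [10,50), [50,inf) ug/L.
* Water is unsuitable for irrigation/aquaculture strictly above 50 ug/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Irrigation / aquaculture acceptable limit for arsenic (ug/L).
IRRIGATION_LIMIT_UGL = 50.0

#: Concentration class lower edges (ug/L); classes are lower-inclusive.
CONC_CLASS_EDGES = (5.0, 10.0, 50.0)

TR_NEGLIGIBLE = 1e-6
TR_UNACCEPTABLE = 1e-4


@dataclass(frozen=True)
class ExposureParams:
    """Ingestion-exposure parameters.

    Units: IR L/day; ED yr; EF day/yr; BW kg; AT day; RfD ug/kg/day;
    CSF (mg/kg/day)^-1; unit_conversion ug->mg.
    """

    IR: float = 1.4
    ED: float = 30.0
    EF: float = 365.0
    BW: float = 64.5
    AT: float = 79.0 * 365.0  # 28,835 days: carcinogenic averaging lifetime
    RfD: float = 0.3
    CSF: float = 1.5
    unit_conversion: float = 1e-3

    def __post_init__(self):
        for name in ("IR", "ED", "EF", "BW", "AT", "RfD", "CSF", "unit_conversion"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.EF > 366:
            raise ValueError("EF cannot exceed 366 day/yr")

    @classmethod
    def from_yaml(cls, path) -> "ExposureParams":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "IR": self.IR, "ED": self.ED, "EF": self.EF, "BW": self.BW,
            "AT": self.AT, "RfD": self.RfD, "CSF": self.CSF,
            "unit_conversion": self.unit_conversion,
        }


def _check_conc(C):
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    return C


def daily_intake(C, p: ExposureParams = ExposureParams()):
    """DI = C * IR / BW (ug/kg/day) for C in ug/L."""
    C = _check_conc(C)
    out = C * p.IR / p.BW
    return out if out.ndim else float(out)


def hazard_quotient(C, p: ExposureParams = ExposureParams()):
    """HQ = DI / RfD (dimensionless)."""
    out = np.asarray(daily_intake(C, p)) / p.RfD
    return out if out.ndim else float(out)


def target_risk(C, p: ExposureParams = ExposureParams()):
    """TR = DI * (EF * ED / AT) * CSF * 1e-3 (lifetime cancer probability)."""
    di = np.asarray(daily_intake(C, p))
    out = di * (p.EF * p.ED / p.AT) * p.CSF * p.unit_conversion
    return out if out.ndim else float(out)


def classify_tr(TR):
    """1 = negligible (TR < 1e-6), 2 = acceptable (1e-6..1e-4 inclusive),
    3 = unacceptable (TR > 1e-4)."""
    TR = np.asarray(TR, dtype=float)
    if np.any(TR < 0):
        raise ValueError("TR must be >= 0")
    lev = np.where(TR < TR_NEGLIGIBLE, 1, np.where(TR <= TR_UNACCEPTABLE, 2, 3))
    return lev if lev.ndim else int(lev)


def classify_hq(HQ):
    """1 = adverse non-carcinogenic effect possible (HQ > 1), 2 = acceptable."""
    HQ = np.asarray(HQ, dtype=float)
    if np.any(HQ < 0):
        raise ValueError("HQ must be >= 0")
    lev = np.where(HQ > 1.0, 1, 2)
    return lev if lev.ndim else int(lev)


def classify_suitability(C):
    """'unsuitable' for irrigation/aquaculture iff C > 50 ug/L (the limit
    itself is acceptable), else 'suitable'."""
    C = _check_conc(C)
    out = np.where(C > IRRIGATION_LIMIT_UGL, "unsuitable", "suitable")
    return out if out.ndim else str(out)


def concentration_class(C):
    """Four-band concentration class: 1 = [0,5), 2 = [5,10), 3 = [10,50),
    4 = [50,inf) ug/L (lower-inclusive)."""
    C = _check_conc(C)
    cls = 1 + np.searchsorted(np.asarray(CONC_CLASS_EDGES), C, side="right")
    return cls if cls.ndim else int(cls)


def risk_layers(conc_ugL, p: ExposureParams = ExposureParams()) -> dict[str, np.ndarray]:
    """All derived risk/classification layers for a concentration array
    (NaN cells propagate as NaN / class 0 / empty suitability)."""
    C = np.asarray(conc_ugL, dtype=float)
    valid = np.isfinite(C)
    Cv = np.where(valid, C, 0.0)
    di = daily_intake(Cv, p)
    hq = hazard_quotient(Cv, p)
    tr = target_risk(Cv, p)
    layers = {
        "DI": np.where(valid, di, np.nan),
        "HQ": np.where(valid, hq, np.nan),
        "TR": np.where(valid, tr, np.nan),
        "hq_level": np.where(valid, classify_hq(hq), 0),
        "tr_level": np.where(valid, classify_tr(tr), 0),
        "conc_class": np.where(valid, concentration_class(Cv), 0),
        "suitability": np.where(valid, classify_suitability(Cv), ""),
    }
    return layers
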