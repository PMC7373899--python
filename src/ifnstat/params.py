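"""Parameter bookkeeping for the IFNα signal-transduction model.

All estimated parameters live on log10 scale (natural values are strictly
positive).  The estimated set for the Huh7.5 configuration decomposes as

* 12 initial abundances (receptor pool, total STAT1/STAT2/IRF9, basal
  SOCS1/SOCS3/IRF2 protein, and five basal mRNA levels),
* 17 observation scalings/offsets,
* 56 dynamical parameters (rate constants, including ``BindIFN``,
  ``synthUSP18`` and the four overexpression/inhibitor parameters),

for a total of 85.  Basal synthesis rates and a handful of degradation rates
are *derived* from the steady-state transform and are not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

GENES = ("STAT1", "STAT2", "IRF9", "IRF2", "USP18", "SOCS1", "SOCS3")

#: dynamical parameters common to every receptor variant (49 of them)
_DYNAMIC_COMMON = (
    # receptor module
    "BindIFN", "KiSOCS", "deactRec", "degRec",
    # lumped phosphorylation/dimerization
    "actSTAT1", "actSTAT2", "KiUSP18",
    # complex handling
    "formISGF3", "impComplex", "dissDimHet", "dissISGF3",
    # monomer shuttling
    "impSTAT1", "impSTAT2", "impIRF9", "expMono",
    # promoter occupancy
    "actGAS", "actISREhet", "actISREISGF3", "decayOcc",
    # transcription (induced rates; basal rates are derived)
    "synthSTAT1mRNA", "synthSTAT2mRNA", "synthIRF9mRNA", "synthIRF2mRNA",
    "synthUSP18mRNA", "synthSOCS1mRNA", "synthSOCS3mRNA",
    "degSTATmRNA", "degIRF9mRNA", "degIRF2mRNA", "degUSP18mRNA",
    "degSOCS1mRNA", "degSOCS3mRNA",
    "KiIRF2", "KmIRF9occ",
    # translation (rates for SOCS1/SOCS3/IRF2 are derived)
    "synthSTAT1", "synthSTAT2", "synthIRF9", "synthUSP18",
    "delaySTAT1", "delaySTAT2", "delayIRF9", "delayIRF2",
    "delayUSP18", "delaySOCS1", "delaySOCS3",
    # feedback-protein degradation
    "degUSP18", "degSOCS1", "degSOCS3", "degIRF2",
)

#: receptor-degradation parameters per structural variant
VARIANT_PARAMS = {
    "SOCS1": ("VdegSOCS1", "Kmdeg"),
    "USP18": ("VdegUSP18", "Kmdeg"),
    "SOCS1xUSP18": ("VdegCoop", "Kmdeg"),
    "SOCS1_or_SOCS1xUSP18": ("VdegSOCS1", "VdegCoop", "Kmdeg"),
}

#: condition-specific parameters for USP18 overexpression / siRNA conditions
OE_INH_PARAMS = (
    "synthUSP18mRNAbasal_OE", "synthUSP18_inh",
    "synthUSP18mRNAbasal_inh", "synthUSP18mRNA_inh",
)

INITIAL_PARAMS = (
    "Rec0", "totSTAT1", "totSTAT2", "totIRF9",
    "SOCS1_0", "SOCS3_0", "IRF2_0",
    "STAT1mRNA0", "STAT2mRNA0", "IRF9mRNA0", "USP18mRNA0", "SOCS1mRNA0",
)

#: basal mRNA levels fixed during model reduction (fold-change observables
#: make them structurally non-identifiable)
FIXED_CONSTANTS = {"SOCS3mRNA0": 1.0, "IRF2mRNA0": 1.0}

SCALING_PARAMS = (
    "scale_pSTAT1_Cyt", "scale_pSTAT2_Cyt", "scale_pSTAT1_Nuc",
    "scale_pSTAT2_Nuc", "scale_tSTAT1_Cyt", "scale_tSTAT2_Cyt",
    "scale_IRF9_Cyt", "scale_USP18_Cyt",
    "offset_pSTAT1_Cyt", "offset_pSTAT2_Cyt",
    "scale_mRNA_STAT1", "scale_mRNA_STAT2", "scale_mRNA_IRF9",
    "scale_mRNA_IRF2", "scale_mRNA_USP18", "scale_mRNA_SOCS1",
    "scale_mRNA_SOCS3",
)

#: abundance-like parameters excluded from cell-type ratio estimation
ABUNDANCE_PARAMS = ("totSTAT1", "totSTAT2", "totIRF9", "synthUSP18")


def dynamic_names(variant: str = "SOCS1_or_SOCS1xUSP18") -> tuple[str, ...]:
    """Names of all dynamical parameters for a receptor variant."""
    if variant not in VARIANT_PARAMS:
        raise ValueError(f"unknown receptor variant {variant!r}")
    return _DYNAMIC_COMMON + VARIANT_PARAMS[variant] + OE_INH_PARAMS


def estimated_names(variant: str = "SOCS1_or_SOCS1xUSP18") -> tuple[str, ...]:
    """All estimated parameters: initials + scalings/offsets + dynamics."""
    return INITIAL_PARAMS + SCALING_PARAMS + dynamic_names(variant)


def l1_eligible_names(variant: str = "SOCS1_or_SOCS1xUSP18",
                      fix_bindifn: bool = False) -> tuple[str, ...]:
    """Parameters eligible for cell-type ratio (elastic-net) estimation.

    Dynamic + initial parameters, excluding the four abundance parameters
    (re-estimated per cell type), the four overexpression/inhibitor
    parameters, and optionally BindIFN when it is held fixed.
    """
    excluded = set(ABUNDANCE_PARAMS) | set(OE_INH_PARAMS)
    if fix_bindifn:
        excluded.add("BindIFN")
    return tuple(n for n in dynamic_names(variant) + INITIAL_PARAMS
                 if n not in excluded)


@dataclass
class ParameterSet:
    """Named log10-scale parameter vector with dict-like access."""

    names: tuple[str, ...]
    log10: np.ndarray
    variant: str = "SOCS1_or_SOCS1xUSP18"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.log10 = np.asarray(self.log10, dtype=float)
        if self.log10.shape != (len(self.names),):
            raise ValueError("parameter vector length mismatch")
        self._index = {n: i for i, n in enumerate(self.names)}
        if len(self._index) != len(self.names):
            raise ValueError("duplicate parameter names")

    @classmethod
    def from_dict(cls, values: dict[str, float],
                  variant: str = "SOCS1_or_SOCS1xUSP18",
                  log10_scale: bool = False) -> "ParameterSet":
        """Build from natural-scale (default) or log10-scale values."""
        names = estimated_names(variant)
        missing = [n for n in names if n not in values]
        if missing:
            raise KeyError(f"missing parameters: {missing}")
        vals = np.array([values[n] for n in names], dtype=float)
        if not log10_scale:
            if np.any(vals <= 0):
                bad = [n for n, v in zip(names, vals) if v <= 0]
                raise ValueError(f"non-positive natural values for {bad}")
            vals = np.log10(vals)
        return cls(names=names, log10=vals, variant=variant)

    def __getitem__(self, name: str) -> float:
        return self.log10[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def natural(self, name: str | None = None):
        if name is None:
            return 10.0 ** self.log10
        return 10.0 ** self.log10[self._index[name]]

    def as_dict(self, natural: bool = True) -> dict[str, float]:
        vals = self.natural() if natural else self.log10
        return dict(zip(self.names, vals))

    def updated(self, changes: dict[str, float],
                log10_scale: bool = False) -> "ParameterSet":
        """Copy with ``changes`` applied (natural scale unless stated)."""
        out = self.log10.copy()
        for name, v in changes.items():
            if name not in self._index:
                raise KeyError(name)
            out[self._index[name]] = v if log10_scale else np.log10(v)
        return ParameterSet(self.names, out, self.variant)

    def shifted(self, deltas: dict[str, float]) -> "ParameterSet":
        """Copy with log10 shifts (cell-type ratio parameters) applied."""
        out = self.log10.copy()
        for name, d in deltas.items():
            if name not in self._index:
                raise KeyError(name)
            out[self._index[name]] += d
        return ParameterSet(self.names, out, self.variant)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"variant": self.variant,
                            "log10": {n: float(v) for n, v in
                                      zip(self.names, self.log10)}}, fh)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["log10"], variant=doc.get(
            "variant", "SOCS1_or_SOCS1xUSP18"), log10_scale=True)
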