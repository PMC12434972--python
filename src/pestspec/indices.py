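"""The vegetation-index bank: 31 conventional + 31 red-edge indices.

Each index is a pure function of the five surface reflectances
(B, G, R, RE, NIR).  Conventional (CONV) indices never touch the
red-edge band; red-edge (RE) indices always do.  Many RE entries are
band-substitution variants of a conventional counterpart:

``<name>reg``
    the red-edge band substituted for NIR in the base formula;
``<name>reg*``
    the red-edge band substituted for red.

The substitution rule is applied mechanically to the registered base
formula, so every ``reg``/``reg*`` value equals its counterpart's
formula under the documented swap by construction.  The remaining RE
entries (lnRE, SCCI, ARI, TCARI, MTCI, CIre, NDSIreg, NDSIreg*) are
intrinsically red-edge indices with their standard literature formulas.

The registry is data-driven: entries can be added, replaced or removed,
and a registry whose total differs from the canonical 62 (31 per
family) only triggers a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

CONV = "CONV"
RE = "RE"

_EPS = 0.0  # guards are explicit, not epsilon-fudged


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral index: family tag, formula and domain guard."""

    name: str
    family: str  # CONV | RE
    formula: Callable[..., np.ndarray]  # f(b, g, r, re, nir)
    guard: Callable[..., np.ndarray] | None = None  # True where defined
    expression: str = ""  # human-readable formula, for the manifest

    def __call__(self, b, g, r, re, nir):
        return self.formula(b, g, r, re, nir)


def _safe(value, defined):
    """NaN-flag samples whose domain guard is violated."""
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.asarray(value, dtype=float)
    out = np.where(defined, v, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


# --- base formulas -----------------------------------------------------
# Written over generic (blue, green, red, nir) so that reg/reg* variants
# can be generated by band substitution.  Each returns (value, defined).

def _ndvi(b, g, r, nir):
    return (nir - r) / (nir + r), nir + r != 0


def _gndvi(b, g, r, nir):
    return (nir - g) / (nir + g), nir + g != 0


def _dvi(b, g, r, nir):
    return nir - r, np.True_


def _gdvi(b, g, r, nir):
    return nir - g, np.True_


def _rvi(b, g, r, nir):
    return nir / r, r != 0


def _ci(b, g, r, nir):
    return nir / g - 1.0, g != 0


def _evi(b, g, r, nir):
    d = nir + 6.0 * r - 7.5 * b + 1.0
    return 2.5 * (nir - r) / d, d != 0


def _evi2(b, g, r, nir):
    d = nir + 2.4 * r + 1.0
    return 2.5 * (nir - r) / d, d != 0


def _savi(b, g, r, nir):
    return 1.5 * (nir - r) / (nir + r + 0.5), np.True_


def _gsavi(b, g, r, nir):
    return 1.5 * (nir - g) / (nir + g + 0.5), np.True_


def _osavi(b, g, r, nir):
    return (nir - r) / (nir + r + 0.16), np.True_


def _msavi(b, g, r, nir):
    t = (2 * nir + 1.0) ** 2 - 8.0 * (nir - r)
    return (2 * nir + 1.0 - np.sqrt(np.maximum(t, 0.0))) / 2.0, t >= 0


def _rdvi(b, g, r, nir):
    s = nir + r
    return (nir - r) / np.sqrt(np.maximum(s, 0.0)), s > 0


def _gli(b, g, r, nir):
    d = 2 * g + r + b
    return (2 * g - r - b) / d, d != 0


def _nli(b, g, r, nir):
    d = nir**2 + r
    return (nir**2 - r) / d, d != 0


def _2nli(b, g, r, nir):
    d = 2 * nir**2 + r
    return (2 * nir**2 - r) / d, d != 0


def _mnli(b, g, r, nir):
    return 1.5 * (nir**2 - r) / (nir**2 + r + 0.5), np.True_


def _gmnli(b, g, r, nir):
    return 1.5 * (nir**2 - g) / (nir**2 + g + 0.5), np.True_


def _wdrvi(b, g, r, nir, alpha=0.12):
    d = alpha * nir + r
    return (alpha * nir - r) / d, d != 0


def _tvi(b, g, r, nir):
    return 0.5 * (120.0 * (nir - g) - 200.0 * (r - g)), np.True_


def _mtvi2(b, g, r, nir):
    t = (2 * nir + 1.0) ** 2 - (6.0 * nir - 5.0 * np.sqrt(np.maximum(r, 0.0))) - 0.5
    num = 1.5 * (1.2 * (nir - g) - 2.5 * (r - g))
    return num / np.sqrt(np.maximum(t, np.finfo(float).tiny)), t > 0


def _msr(b, g, r, nir):
    sr = nir / np.where(r == 0, np.nan, r)
    return (sr - 1.0) / np.sqrt(sr + 1.0), (r != 0) & (nir / np.where(r == 0, 1, r) >= -1)


def _arvi(b, g, r, nir):
    rb = 2.0 * r - b
    d = nir + rb
    return (nir - rb) / d, d != 0


def _vari(b, g, r, nir):
    d = g + r - b
    return (g - r) / d, d != 0


def _grvi(b, g, r, nir):
    d = g + r
    return (g - r) / d, d != 0


def _sipi(b, g, r, nir):
    d = nir - r
    return (nir - b) / d, d != 0


def _tgi(b, g, r, nir):
    return g - 0.39 * r - 0.61 * b, np.True_


def _ngbdi(b, g, r, nir):
    d = g + b
    return (g - b) / d, d != 0


def _si(b, g, r, nir):
    return nir / b, b != 0


def _si1(b, g, r, nir):
    return b / r, r != 0


def _int2(b, g, r, nir):
    return (g + r + nir) / 3.0, np.True_


_BASE: dict[str, tuple[Callable, str]] = {
    "NDVI": (_ndvi, "(NIR - R) / (NIR + R)"),
    "GNDVI": (_gndvi, "(NIR - G) / (NIR + G)"),
    "DVI": (_dvi, "NIR - R"),
    "GDVI": (_gdvi, "NIR - G"),
    "RVI": (_rvi, "NIR / R"),
    "CI": (_ci, "NIR / G - 1"),
    "EVI": (_evi, "2.5 (NIR - R) / (NIR + 6R - 7.5B + 1)"),
    "EVI2": (_evi2, "2.5 (NIR - R) / (NIR + 2.4R + 1)"),
    "SAVI": (_savi, "1.5 (NIR - R) / (NIR + R + 0.5)"),
    "GSAVI": (_gsavi, "1.5 (NIR - G) / (NIR + G + 0.5)"),
    "OSAVI": (_osavi, "(NIR - R) / (NIR + R + 0.16)"),
    "MSAVI": (_msavi, "(2NIR + 1 - sqrt((2NIR+1)^2 - 8(NIR-R))) / 2"),
    "RDVI": (_rdvi, "(NIR - R) / sqrt(NIR + R)"),
    "GLI": (_gli, "(2G - R - B) / (2G + R + B)"),
    "NLI": (_nli, "(NIR^2 - R) / (NIR^2 + R)"),
    "2NLI": (_2nli, "(2NIR^2 - R) / (2NIR^2 + R)"),
    "MNLI": (_mnli, "1.5 (NIR^2 - R) / (NIR^2 + R + 0.5)"),
    "GMNLI": (_gmnli, "1.5 (NIR^2 - G) / (NIR^2 + G + 0.5)"),
    "WDRVI": (_wdrvi, "(0.12 NIR - R) / (0.12 NIR + R)"),
    "TVI": (_tvi, "0.5 (120 (NIR - G) - 200 (R - G))"),
    "MTVI2": (
        _mtvi2,
        "1.5 (1.2(NIR-G) - 2.5(R-G)) / sqrt((2NIR+1)^2 - (6NIR - 5 sqrt(R)) - 0.5)",
    ),
    "MSR": (_msr, "(NIR/R - 1) / sqrt(NIR/R + 1)"),
    "ARVI": (_arvi, "(NIR - (2R - B)) / (NIR + (2R - B))"),
    "VARI": (_vari, "(G - R) / (G + R - B)"),
    "GRVI": (_grvi, "(G - R) / (G + R)"),
    "SIPI": (_sipi, "(NIR - B) / (NIR - R)"),
    "TGI": (_tgi, "G - 0.39 R - 0.61 B"),
    "NGBDI": (_ngbdi, "(G - B) / (G + B)"),
    "SI": (_si, "NIR / B"),
    "SI1": (_si1, "B / R"),
    "Int2": (_int2, "(G + R + NIR) / 3"),
}

#: CONV bases whose red-edge-for-NIR variant ("reg") is registered
_REG = [
    "NDVI", "DVI", "RVI", "EVI", "SAVI", "OSAVI", "MSAVI", "RDVI", "NLI",
    "MNLI", "WDRVI", "TVI", "MTVI2", "MSR", "GNDVI", "GSAVI", "SI",
]
#: CONV bases whose red-edge-for-red variant ("reg*") is registered
_REG_STAR = ["NDVI", "DVI", "RVI", "EVI", "SI1", "Int2"]


def _conv_def(name: str) -> IndexDefinition:
    func, expr = _BASE[name]

    def formula(b, g, r, re, nir, _f=func):
        with np.errstate(divide="ignore", invalid="ignore"):
            v, ok = _f(b, g, r, nir)
        return _safe(v, ok)

    return IndexDefinition(name, CONV, formula, expression=expr)


def _reg_def(name: str) -> IndexDefinition:
    func, expr = _BASE[name]

    def formula(b, g, r, re, nir, _f=func):
        with np.errstate(divide="ignore", invalid="ignore"):
            v, ok = _f(b, g, r, re)  # RE substituted for NIR
        return _safe(v, ok)

    return IndexDefinition(
        name + "reg", RE, formula, expression=expr + "  [NIR -> RE]"
    )


def _reg_star_def(name: str) -> IndexDefinition:
    func, expr = _BASE[name]

    def formula(b, g, r, re, nir, _f=func):
        with np.errstate(divide="ignore", invalid="ignore"):
            v, ok = _f(b, g, re, nir)  # RE substituted for red
        return _safe(v, ok)

    return IndexDefinition(
        name + "reg*", RE, formula, expression=expr + "  [R -> RE]"
    )


# --- intrinsic red-edge indices ---------------------------------------

def _lnre(b, g, r, re, nir):
    return _safe(np.log(np.where(re > 0, 1.0 / np.where(re > 0, re, 1.0), np.nan)), re > 0)


def _scci(b, g, r, re, nir):
    ndre_d = nir + re
    ndvi_d = nir + r
    ndvi = (nir - r) / np.where(ndvi_d == 0, np.nan, ndvi_d)
    ok = (ndre_d != 0) & (ndvi_d != 0) & (nir != r)
    return _safe((nir - re) / np.where(ndre_d == 0, np.nan, ndre_d) / ndvi, ok)


def _ari(b, g, r, re, nir):
    return _safe(1.0 / np.where(g == 0, np.nan, g) - 1.0 / np.where(re == 0, np.nan, re), (g != 0) & (re != 0))


def _tcari(b, g, r, re, nir):
    ok = r != 0
    return _safe(
        3.0 * ((re - r) - 0.2 * (re - g) * (re / np.where(r == 0, np.nan, r))), ok
    )


def _mtci(b, g, r, re, nir):
    d = re - r
    return _safe((nir - re) / np.where(d == 0, np.nan, d), d != 0)


def _cire(b, g, r, re, nir):
    return _safe(nir / np.where(re == 0, np.nan, re) - 1.0, re != 0)


def _ndsireg(b, g, r, re, nir):
    d = r + re
    return _safe((r - re) / np.where(d == 0, np.nan, d), d != 0)


def _ndsireg_star(b, g, r, re, nir):
    d = re + nir
    return _safe((re - nir) / np.where(d == 0, np.nan, d), d != 0)


_INTRINSIC_RE = [
    IndexDefinition("lnRE", RE, _lnre, expression="ln(1 / RE)"),
    IndexDefinition("SCCI", RE, _scci, expression="NDRE / NDVI"),
    IndexDefinition("ARI", RE, _ari, expression="1/G - 1/RE"),
    IndexDefinition(
        "TCARI", RE, _tcari, expression="3 ((RE - R) - 0.2 (RE - G) (RE / R))"
    ),
    IndexDefinition("MTCI", RE, _mtci, expression="(NIR - RE) / (RE - R)"),
    IndexDefinition("CIre", RE, _cire, expression="NIR / RE - 1"),
    IndexDefinition("NDSIreg", RE, _ndsireg, expression="(R - RE) / (R + RE)"),
    IndexDefinition(
        "NDSIreg*", RE, _ndsireg_star, expression="(RE - NIR) / (RE + NIR)"
    ),
]


def default_registry() -> dict[str, IndexDefinition]:
    """The canonical 62-entry registry: 31 CONV + 31 RE, names unique."""
    reg: dict[str, IndexDefinition] = {}
    for name in _BASE:
        reg[name] = _conv_def(name)
    for name in _REG:
        d = _reg_def(name)
        reg[d.name] = d
    for name in _REG_STAR:
        d = _reg_star_def(name)
        reg[d.name] = d
    for d in _INTRINSIC_RE:
        reg[d.name] = d
    return reg


def validate_registry(registry: Mapping[str, IndexDefinition]) -> None:
    """Warn (not raise) when the registry departs from the canonical bank."""
    conv = sum(1 for d in registry.values() if d.family == CONV)
    re_ = sum(1 for d in registry.values() if d.family == RE)
    if conv != 31 or re_ != 31:
        warnings.warn(
            f"registry has {conv} CONV + {re_} RE indices "
            "(canonical bank is 31 + 31)",
            stacklevel=2,
        )


def compute_index(name: str, bands, registry=None):
    """Evaluate one registered index on a 5-band reflectance vector/stack.

    ``bands`` is (B, G, R, RE, NIR), scalars or arrays.  Samples whose
    domain guard fails come back as NaN (flagged not-computable); the
    feature-table builder decides whether to drop or impute them.
    """
    registry = registry if registry is not None else default_registry()
    if name not in registry:
        raise KeyError(f"unknown index {name!r}")
    b, g, r, re, nir = (np.asarray(x, dtype=float) for x in bands)
    return registry[name](b, g, r, re, nir)


def registry_manifest(registry=None) -> list[dict]:
    """JSON-serialisable record of every formula in the registry."""
    registry = registry if registry is not None else default_registry()
    return [
        {"name": d.name, "family": d.family, "formula": d.expression}
        for d in registry.values()
    ]
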