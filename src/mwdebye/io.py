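"""Plain-text readers and writers: spectrum CSV, model JSON, fit JSON.

CSV dialect: comma-separated, '.' decimal, UTF-8, '#' comment lines, header
``frequency_hz,eps_real,eps_imag[,eps_imag_ac]``.  Floats are serialised with
17 significant digits so round trips are lossless.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterDomainError, SpectrumValidationError
from .fitting import FitResult
from .mwdist import MWParameters, SpeciesComponent
from .permittivity import EPS0_PAPER, DielectricModel, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_model",
    "write_model",
    "write_fit",
    "read_fit",
]

_SPECTRUM_COLUMNS = ("frequency_hz", "eps_real", "eps_imag")


def read_spectrum(path, sigma_dc: float | None = None, eps0: float = EPS0_PAPER) -> Spectrum:
    """Read a spectrum CSV; '#'-prefixed lines are skipped.

    When ``eps_imag_ac`` is absent it is recomputed if ``sigma_dc`` is given.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True,
                            float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise SpectrumValidationError(f"{path}: cannot parse spectrum CSV: {exc}") from exc
    missing = [c for c in _SPECTRUM_COLUMNS if c not in frame.columns]
    if missing:
        raise SpectrumValidationError(
            f"{path}: missing required columns {missing}; header must start with "
            f"{','.join(_SPECTRUM_COLUMNS)}"
        )
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number) or frame[col].isna().any():
            bad = int(frame.index[frame[col].isna() | ~frame[col].apply(np.isreal)][0]) + 2
            raise SpectrumValidationError(f"{path}: malformed value in column {col!r} near line {bad}")
    ac = None
    if "eps_imag_ac" in frame.columns:
        ac = frame["eps_imag_ac"].to_numpy(float)
    elif sigma_dc is not None:
        w = 2.0 * math.pi * frame["frequency_hz"].to_numpy(float)
        ac = frame["eps_imag"].to_numpy(float) - sigma_dc / (w * eps0)
    return Spectrum(
        frequency_hz=frame["frequency_hz"].to_numpy(float),
        eps_real=frame["eps_real"].to_numpy(float),
        eps_imag=frame["eps_imag"].to_numpy(float),
        eps_imag_ac=ac,
    )


def write_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    cols = {
        "frequency_hz": spectrum.frequency_hz,
        "eps_real": spectrum.eps_real,
        "eps_imag": spectrum.eps_imag,
    }
    if spectrum.eps_imag_ac is not None:
        cols["eps_imag_ac"] = spectrum.eps_imag_ac
    # %.17g round-trips float64 exactly; pandas keeps large spectra fast
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def _model_to_dict(model: DielectricModel) -> dict:
    return {
        "eps_inf": model.eps_inf,
        "delta_eps": model.delta_eps,
        "sigma_dc": model.sigma_dc,
        "eps0": model.eps0,
        "components": [
            {
                "label": comp.label,
                "r": comp.weight,
                "ts_seconds": comp.params.ts,
                "tau_c_seconds": comp.params.tau_c,
            }
            for comp in model.components
        ],
    }


def _model_from_dict(payload: dict, source: str = "<dict>") -> DielectricModel:
    required = {"eps_inf", "delta_eps", "sigma_dc", "components"}
    missing = required - payload.keys()
    if missing:
        raise ParameterDomainError(f"{source}: model config missing keys {sorted(missing)}")
    comps = []
    for i, entry in enumerate(payload["components"]):
        entry_missing = {"r", "ts_seconds", "tau_c_seconds"} - entry.keys()
        if entry_missing:
            raise ParameterDomainError(
                f"{source}: component {i} missing keys {sorted(entry_missing)}"
            )
        comps.append(
            SpeciesComponent(
                params=MWParameters.from_spectroscopy(
                    ts=float(entry["ts_seconds"]), tau_c=float(entry["tau_c_seconds"])
                ),
                weight=float(entry["r"]),
                label=str(entry.get("label", f"species{i}")),
            )
        )
    return DielectricModel(
        eps_inf=float(payload["eps_inf"]),
        delta_eps=float(payload["delta_eps"]),
        sigma_dc=float(payload["sigma_dc"]),
        components=tuple(comps),
        eps0=float(payload.get("eps0", EPS0_PAPER)),
    )


def read_model(path) -> DielectricModel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParameterDomainError(f"{path}: invalid JSON: {exc}") from exc
    return _model_from_dict(payload, source=str(path))


def write_model(model: DielectricModel, path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(_model_to_dict(model), fh, indent=2)
        fh.write("\n")


def write_fit(result: FitResult, path) -> None:
    payload = {
        "model": _model_to_dict(result.model),
        "params": result.params,
        "stderr": result.stderr,
        "loss": result.loss,
        "success": result.success,
        "warnings": list(result.warnings),
        "starts": result.starts,
        "options": {
            "targets": result.options.targets,
            "loss_space": result.options.loss_space,
            "method": result.options.method,
            "model_kind": result.options.model_kind,
            "multi_start": result.options.multi_start,
            "seed": result.options.seed,
        },
    }
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_fit(path) -> dict:
    with open(Path(path), encoding="utf-8") as fh:
        return json.load(fh)
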