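"""Orchestration: annotate runs, semiquantify oxidation, compare RP vs BS.

This module strings the pieces together the way the comparability design
demands:

1. :func:`assign_run` — detect chromatographic peaks, average and deconvolute
   each window, match zero-charge masses against the proteoform library at
   ±70 ppm, annotate with star notation, order coeluting species by intensity.
2. :func:`relative_abundance` / :func:`measure_relative_abundance` — the EIC
   semiquantification statistic ar = I_nox / (I_0ox + I_nox) for a chosen
   oxidation level against the unoxidized form of the same subunit.
3. :func:`time_course` — ar by treatment duration with per-replicate points.
4. :func:`attribute_sites` — methionine-site attribution by cross-mAb
   set-difference reasoning over most-abundant oxidation counts.
5. :func:`biosimilarity_report` — side-by-side species tables, ar deltas and
   attributions for a reference-product / biosimilar pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import PROTON_MASS
from .deconv import (
    DeconvolutedPeak,
    average_spectrum,
    centroid_peaks,
    deconvolute,
    detect_chromatographic_peaks,
    extract_eic,
)
from .mab_model import MAbDefinition, MapComparison, SubunitChain
from .proteoforms import (
    Assignment,
    LibraryConfig,
    Proteoform,
    enumerate_proteoforms,
    match_mass,
)
from .simulate import ChromatographicRun

#: default ar report configuration: oxidation level per (mAb, subunit).
#: Only the bevacizumab time course is quantified by default (LC 3ox and
#: Fd' 3ox against the unoxidized forms); for the infliximab-like product the
#: Fab subunits convert completely, leaving no meaningful 0-ox reference, and
#: the residual 0-ox EIC is dominated by the isobaric pyroglutamate + 1 ox
#: form (-17 + 16 ≈ -1 Da), so ar levels there are an explicit user choice.
DEFAULT_AR_LEVELS: dict[str, dict[str, int]] = {
    "bevacizumab-like": {"LC": 3, "Fd'": 3},
}


@dataclass
class PeakAnnotation:
    """Assignments of one chromatographic window, strongest first."""

    rt_window: tuple[float, float]
    assignments: list[Assignment]
    peaks: list[DeconvolutedPeak]          # aligned with assignments
    unmatched: list[tuple[float, float]]   # (mass, abundance) with no library hit
    subunit_kind: str | None               # majority call by summed abundance


@dataclass(frozen=True)
class RelAbundanceRecord:
    """One ar measurement: subunit n-ox vs 0-ox EIC peak heights."""

    mab_name: str
    role: str
    subunit: str
    ox_level: int
    duration: float
    replicate: int
    i_0ox: float
    i_nox: float
    ar: float
    flagged: bool = False


@dataclass(frozen=True)
class SiteAttribution:
    """Verdict for one methionine site with its reasoning trail."""

    mab_name: str
    subunit_kind: str
    site_label: str
    verdict: str   # susceptible | resistant | indeterminate
    evidence: str


def build_libraries(
    subunits: dict[str, SubunitChain], config: LibraryConfig | None = None
) -> dict[str, list[Proteoform]]:
    """Proteoform search library per subunit kind."""
    return {kind: enumerate_proteoforms(s, config) for kind, s in subunits.items()}


def assign_run(
    run: ChromatographicRun,
    libraries: dict[str, list[Proteoform]],
    tol_ppm: float = 70.0,
) -> list[PeakAnnotation]:
    """Identify species in every detected chromatographic peak of a run."""
    combined = [pf for lib in libraries.values() for pf in lib]
    annotations: list[PeakAnnotation] = []
    for window in detect_chromatographic_peaks(run):
        spec = average_spectrum(run, window)
        centroids = centroid_peaks(spec)
        peaks = deconvolute(centroids)
        assignments: list[Assignment] = []
        kept_peaks: list[DeconvolutedPeak] = []
        unmatched: list[tuple[float, float]] = []
        for peak in peaks:
            hits = match_mass(
                peak.zero_charge_mass, combined, tol_ppm, abundance=peak.abundance
            )
            if hits:
                assignments.append(hits[0])
                kept_peaks.append(peak)
            else:
                unmatched.append((peak.zero_charge_mass, peak.abundance))
        order = sorted(
            range(len(assignments)), key=lambda i: -assignments[i].abundance
        )
        assignments = [assignments[i] for i in order]
        kept_peaks = [kept_peaks[i] for i in order]
        by_kind: dict[str, float] = {}
        for a in assignments:
            k = a.proteoform.subunit_kind
            by_kind[k] = by_kind.get(k, 0.0) + a.abundance
        majority = max(by_kind, key=by_kind.get) if by_kind else None
        annotations.append(
            PeakAnnotation(
                rt_window=window,
                assignments=assignments,
                peaks=kept_peaks,
                unmatched=unmatched,
                subunit_kind=majority,
            )
        )
    return annotations


def most_abundant_species(
    annotations: list[PeakAnnotation], subunit: str
) -> Proteoform:
    """The subunit's highest-abundance assignment across all windows.

    Exact abundance ties break toward the lower oxidation count, then the
    lexically smaller name.
    """
    candidates = [
        a
        for ann in annotations
        for a in ann.assignments
        if a.proteoform.subunit_kind == subunit
    ]
    if not candidates:
        raise ValueError(f"subunit {subunit!r} not present in any annotation")
    best = sorted(
        candidates,
        key=lambda a: (
            -a.abundance,
            a.proteoform.mods.n_ox,
            a.proteoform.display_name,
        ),
    )[0]
    return best.proteoform


def species_calls(annotations: list[PeakAnnotation]) -> dict[str, Proteoform]:
    """Most abundant species per subunit kind present in the annotations."""
    kinds = {
        a.proteoform.subunit_kind
        for ann in annotations
        for a in ann.assignments
    }
    return {k: most_abundant_species(annotations, k) for k in sorted(kinds)}


def relative_abundance(i_0ox: float, i_nox: float) -> float:
    """ar = I_nox / (I_0ox + I_nox), the oxidized fraction of a species pair."""
    if i_0ox < 0 or i_nox < 0:
        raise ValueError("intensities must be >= 0")
    if i_0ox + i_nox == 0:
        raise ZeroDivisionError("both intensities are zero; ar undefined")
    return i_nox / (i_0ox + i_nox)


def _plain_form(library: list[Proteoform], n_ox: int) -> Proteoform:
    for pf in library:
        m = pf.mods
        if (
            m.n_ox == n_ox
            and m.glycan is None
            and not m.pyroglu
            and not m.cterm_lys
        ):
            return pf
    raise ValueError(f"no unmodified {n_ox}-ox form in library")


def _subunit_window(
    annotations: list[PeakAnnotation], subunit: str
) -> tuple[float, float] | None:
    windows = [
        ann.rt_window for ann in annotations if ann.subunit_kind == subunit
    ]
    if not windows:
        return None
    return (min(w[0] for w in windows), max(w[1] for w in windows))


def _species_apex_charge(
    annotations: list[PeakAnnotation], pf: Proteoform
) -> int | None:
    for ann in annotations:
        for a, peak in zip(ann.assignments, ann.peaks):
            if a.proteoform is pf or a.proteoform.display_name == pf.display_name:
                return peak.apex_charge
    return None


def measure_relative_abundance(
    run: ChromatographicRun,
    annotations: list[PeakAnnotation],
    libraries: dict[str, list[Proteoform]],
    subunit: str,
    ox_level: int,
    tol: float = 0.01,
    window_margin: float = 1.0,
) -> RelAbundanceRecord:
    """EIC-based ar for one subunit/oxidation level of one run.

    The most intense charge state is taken from the deconvolution result when
    the species was assigned, otherwise from the theoretical envelope apex
    z* = round(M/1200). Peak heights are read inside the union RT window of
    the subunit's annotations, widened by ``window_margin`` minutes on both
    sides: a subunit's oxidized states are only partially separated from its
    main peak, so the union window plus margin covers the whole family.
    """
    lib = libraries[subunit]
    pf0 = _plain_form(lib, 0)
    pfn = _plain_form(lib, ox_level)
    window = _subunit_window(annotations, subunit)
    if window is not None:
        window = (window[0] - window_margin, window[1] + window_margin)
    heights = []
    for pf in (pf0, pfn):
        z = _species_apex_charge(annotations, pf)
        if z is None:
            z = int(round(pf.avg_mass / run.acquisition.mass_per_charge))
        mz_center = (pf.avg_mass + z * PROTON_MASS) / z
        trace = extract_eic(run, mz_center, z, tol=tol, rt_window=window)
        heights.append(trace.peak_height)
    i0, i_n = heights
    flagged = i0 + i_n == 0
    ar = 0.0 if flagged else relative_abundance(i0, i_n)
    return RelAbundanceRecord(
        mab_name=run.mab_name,
        role=run.role,
        subunit=subunit,
        ox_level=ox_level,
        duration=run.duration,
        replicate=run.replicate,
        i_0ox=i0,
        i_nox=i_n,
        ar=ar,
        flagged=flagged,
    )


def records_table(records: list[RelAbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mab_name": r.mab_name,
                "role": r.role,
                "subunit": r.subunit,
                "ox_level": r.ox_level,
                "duration": r.duration,
                "replicate": r.replicate,
                "I_0ox": r.i_0ox,
                "I_nox": r.i_nox,
                "ar": r.ar,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )


def time_course(records: list[RelAbundanceRecord]) -> pd.DataFrame:
    """ar by duration per (mAb, role, subunit, level), with replicate spread.

    Individual replicate points are preserved in ``points``; the summary adds
    mean, standard deviation and a per-series monotonicity diagnostic (is the
    replicate-mean ar non-decreasing with treatment duration?).
    """
    df = records_table(records)
    if df.empty:
        return df
    if df["duration"].nunique() < 2:
        raise ValueError("time course needs at least two treatment durations")
    grouped = (
        df.groupby(["mab_name", "role", "subunit", "ox_level", "duration"])["ar"]
        .agg(points=lambda s: tuple(round(v, 6) for v in s), mean="mean", sd="std", n="size")
        .reset_index()
    )
    grouped["monotone_series"] = False
    for key, sub in grouped.groupby(["mab_name", "role", "subunit", "ox_level"]):
        means = sub.sort_values("duration")["mean"].to_numpy()
        grouped.loc[sub.index, "monotone_series"] = bool(
            np.all(np.diff(means) >= -1e-12)
        )
    return grouped


def attribute_sites(
    calls_a: dict[str, int],
    calls_b: dict[str, int],
    subunits_a: dict[str, SubunitChain],
    subunits_b: dict[str, SubunitChain],
    comparison: dict[str, MapComparison],
    names: tuple[str, str],
    equivalences: tuple[tuple[str, str, str], ...] = (),
) -> list[SiteAttribution]:
    """Methionine-site verdicts from most-abundant oxidation counts.

    Per subunit of each mAb: if the most abundant oxidation count equals the
    methionine count, all sites are susceptible; if it is zero, all are
    resistant; otherwise sites proven resistant through the other mAb's
    shared-site evidence are subtracted and the remainder is attributed only
    when uniquely determined. Anything not forced by these rules is
    indeterminate. Every site of both mAbs receives exactly one verdict.
    """
    name_a, name_b = names
    mabs = {
        name_a: (calls_a, subunits_a, name_b),
        name_b: (calls_b, subunits_b, name_a),
    }
    # label equivalence lookup in both directions: (kind, label) -> other label
    equiv: dict[tuple[str, str, str], str] = {}
    for kind, la, lb in equivalences:
        equiv[(name_a, kind, la)] = lb
        equiv[(name_b, kind, lb)] = la

    verdicts: dict[tuple[str, str, str], tuple[str, str]] = {}

    def _set(mab: str, kind: str, label: str, verdict: str, evidence: str) -> None:
        key = (mab, kind, label)
        if key in verdicts and verdicts[key][0] != verdict:
            verdicts[key] = (
                "indeterminate",
                f"conflict: {verdicts[key][1]} vs {evidence}",
            )
        else:
            verdicts[key] = (verdict, evidence)

    deferred: list[tuple[str, str, int]] = []
    for mab, (calls, subunits, _) in mabs.items():
        for kind, subunit in subunits.items():
            labels = subunit.site_labels
            if not labels:
                continue
            n = calls.get(kind)
            if n is None:
                for label in labels:
                    _set(mab, kind, label, "indeterminate", "no species call")
                continue
            if n >= len(labels):
                for label in labels:
                    _set(
                        mab, kind, label, "susceptible",
                        f"{mab} {kind} most abundant species is {n}-ox with "
                        f"{len(labels)} methionines: all sites oxidized",
                    )
            elif n == 0:
                for label in labels:
                    _set(
                        mab, kind, label, "resistant",
                        f"{mab} {kind} most abundant species is unoxidized",
                    )
            else:
                deferred.append((mab, kind, n))

    for mab, kind, n in deferred:
        calls, subunits, other = mabs[mab]
        labels = list(subunits[kind].site_labels)
        resolved_resistant = []
        for label in labels:
            other_label = (
                label
                if (other, kind, label) in verdicts
                else equiv.get((mab, kind, label))
            )
            if other_label is None:
                continue
            ov = verdicts.get((other, kind, other_label))
            if ov and ov[0] == "resistant":
                resolved_resistant.append((label, other_label))
        resistant_labels = {lab for lab, _ in resolved_resistant}
        remainder = [lab for lab in labels if lab not in resistant_labels]
        for lab, other_lab in resolved_resistant:
            _set(
                mab, kind, lab, "resistant",
                f"shared site: {other} {kind} {other_lab} proven resistant",
            )
        if len(remainder) == n:
            for lab in remainder:
                _set(
                    mab, kind, lab, "susceptible",
                    f"{mab} {kind} is {n}-ox; after subtracting shared "
                    f"resistant sites {sorted(resistant_labels)} the oxidation "
                    f"is uniquely attributed to {remainder}",
                )
        else:
            for lab in remainder:
                _set(
                    mab, kind, lab, "indeterminate",
                    f"{mab} {kind} {n}-ox cannot be uniquely distributed over "
                    f"{remainder}",
                )

    out = []
    for mab, (calls, subunits, _) in mabs.items():
        for kind, subunit in subunits.items():
            for label in subunit.site_labels:
                verdict, evidence = verdicts[(mab, kind, label)]
                out.append(
                    SiteAttribution(
                        mab_name=mab,
                        subunit_kind=kind,
                        site_label=label,
                        verdict=verdict,
                        evidence=evidence,
                    )
                )
    return out


def _species_table(annotations: list[PeakAnnotation]) -> list[dict]:
    rows = []
    for ann in annotations:
        for a in ann.assignments:
            rows.append(
                {
                    "subunit": a.proteoform.subunit_kind,
                    "species": a.proteoform.display_name,
                    "observed_mass": round(a.observed_mass, 3),
                    "delta_da": round(a.delta_da, 3),
                    "stars": a.stars,
                    "abundance": round(a.abundance, 3),
                }
            )
    rows.sort(key=lambda r: (r["subunit"], -r["abundance"], r["species"]))
    return rows


def biosimilarity_report(
    mab_name: str,
    unstressed: dict[str, list[PeakAnnotation]],
    stressed: dict[str, list[PeakAnnotation]],
    records: list[RelAbundanceRecord],
    attributions: list[SiteAttribution] | None = None,
) -> dict:
    """Side-by-side RP/BS comparison document (JSON-serializable).

    ``unstressed`` and ``stressed`` map role -> annotations of a representative
    run. The difference list names species assigned in only one product and
    the per-duration ar deltas (BS - RP, replicate means).
    """
    tables = {
        "unstressed": {role: _species_table(anns) for role, anns in unstressed.items()},
        "stressed": {role: _species_table(anns) for role, anns in stressed.items()},
    }
    differences: dict = {}
    for phase in ("unstressed", "stressed"):
        sp = {
            role: {row["species"] for row in rows}
            for role, rows in tables[phase].items()
        }
        if {"RP", "BS"} <= set(sp):
            differences[phase] = {
                "only_in_RP": sorted(sp["RP"] - sp["BS"]),
                "only_in_BS": sorted(sp["BS"] - sp["RP"]),
            }
    ar_deltas = []
    df = records_table(records)
    if not df.empty and {"RP", "BS"} <= set(df["role"]):
        means = (
            df.groupby(["subunit", "ox_level", "duration", "role"])["ar"]
            .mean()
            .unstack("role")
        )
        for (subunit, level, duration), row in means.iterrows():
            if pd.notna(row.get("RP")) and pd.notna(row.get("BS")):
                ar_deltas.append(
                    {
                        "subunit": subunit,
                        "ox_level": int(level),
                        "duration": float(duration),
                        "ar_RP": round(float(row["RP"]), 6),
                        "ar_BS": round(float(row["BS"]), 6),
                        "delta": round(float(row["BS"] - row["RP"]), 6),
                    }
                )
    report = {
        "mab_name": mab_name,
        "species": tables,
        "differences": differences,
        "ar_time_course": [
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in rec.items()}
            for rec in df.to_dict("records")
        ],
        "ar_deltas": ar_deltas,
    }
    if attributions is not None:
        report["site_attributions"] = [
            {
                "mab_name": s.mab_name,
                "subunit": s.subunit_kind,
                "site": s.site_label,
                "verdict": s.verdict,
                "evidence": s.evidence,
            }
            for s in attributions
        ]
    return report
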