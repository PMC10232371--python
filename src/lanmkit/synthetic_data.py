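"""Seeded generators for every input the pipeline consumes.

Each generator emulates one experimental data stream - planted-motif
sequence sets, chelator-buffered titrations, dilution-ITC heat series,
luminescence decay series, two-metal elution profiles and idealized metal
sites - and returns machine-readable ground truth alongside the data, so
every downstream fit and scan can be verified at its exact noise level
(including noise zero, where recovery must be essentially exact).

One top-level seed fans out to independent per-generator streams through a
CRC-based label hash, so adding a generator never perturbs the fixtures of
an existing one.  Outputs use the same standard formats the real pipeline
reads (FASTA, CSV-ready arrays, PDB).
"""

from __future__ import annotations

import zlib

import numpy as np

from .binding_models import BufferSystem, TitrationDataset, free_metal, hill_signal
from .luminescence import DecayTrace, SolventSeries
from .oligomer_state import ITCExperiment, default_injection_schedule, itc_forward
from .separation import SeparationTable
from .seq_screen import LOOP_LENGTH, ProteinRecord

__all__ = [
    "derive_seed",
    "gen_lanm_sequences",
    "gen_titration",
    "gen_itc",
    "gen_decay_series",
    "gen_elution",
    "gen_metal_site",
]

# letters that can never satisfy a default loop-position class, so planted
# loops are the only matches in a generated sequence
_BACKGROUND = "AGKLVFRIQWHM"


def derive_seed(seed: int, label: str) -> int:
    """Independent per-generator stream seed (< 2**31) from a master seed."""
    return zlib.crc32(f"{seed}:{label}".encode()) & 0x7FFFFFFF


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, label))


def _loop(rng: np.random.Generator, p2: bool, broken: bool) -> str:
    """One 12-residue EF-hand loop; ``broken`` destroys position 12."""
    bg = lambda: rng.choice(list(_BACKGROUND))  # noqa: E731
    res = [bg() for _ in range(LOOP_LENGTH)]
    res[0] = "N"
    res[1] = "P" if p2 else bg()
    res[2] = "D"
    res[4] = "T"
    res[8] = "E"
    res[11] = bg() if broken else "E"
    return "".join(res)


def gen_lanm_sequences(
    n: int = 10,
    *,
    hands: int = 4,
    spacings: tuple[int, ...] = (12, 13, 12),
    p2: bool = True,
    decoy_fraction: float = 0.0,
    length: int = 110,
    prefix: int = 8,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[dict]]:
    """Sequences with planted EF-hand loops at recorded offsets, plus truth.

    Each record plants ``hands`` loops separated by ``spacings`` residues
    (mature-lanmodulin geometry by default: 4 hands, 12-13 apart, P2 on).
    A ``decoy_fraction`` of records get every loop's position 12 scrambled,
    so the scanner must find nothing.  Truth records the planted offsets
    (1-based loop starts) and the expected screen verdict.
    """
    if len(spacings) != max(hands - 1, 0):
        raise ValueError("need one spacing per adjacent loop pair")
    min_len = prefix + hands * LOOP_LENGTH + sum(spacings)
    if length < min_len:
        raise ValueError(f"length {length} cannot hold the motif plan (needs >= {min_len})")
    rng = _rng(seed, "sequences")
    records, truth = [], []
    n_decoys = int(round(n * decoy_fraction))
    for i in range(n):
        is_decoy = i < n_decoys
        parts = [ "".join(rng.choice(list(_BACKGROUND)) for _ in range(prefix)) ]
        starts = []
        pos = prefix
        for h in range(hands):
            starts.append(pos + 1)  # 1-based
            parts.append(_loop(rng, p2, broken=is_decoy))
            pos += LOOP_LENGTH
            if h < hands - 1:
                spacer = "".join(rng.choice(list(_BACKGROUND)) for _ in range(spacings[h]))
                parts.append(spacer)
                pos += spacings[h]
        tail = length - pos
        parts.append("".join(rng.choice(list(_BACKGROUND)) for _ in range(tail)))
        seq = "".join(parts)
        rid = f"{'decoy' if is_decoy else 'lanm'}_{i:03d}"
        records.append(ProteinRecord(rid, seq))
        # expected verdict under the default screen criteria (P2 required)
        expected_pass = (
            not is_decoy
            and hands >= 4
            and length < 200
            and p2
            and (min(spacings) <= 13 if spacings else False)
        )
        truth.append(
            {
                "id": rid,
                "seed": seed,
                "decoy": is_decoy,
                "loop_starts": [] if is_decoy else starts,
                "n_hands_expected": 0 if is_decoy else hands,
                "expected_verdict": "pass" if expected_pass else "fail",
            }
        )
    return records, truth


def gen_titration(
    K_d: float,
    hill_n: float,
    *,
    n_points: int = 12,
    span: tuple[float, float] | None = None,
    span_decades: float = 4.0,
    S0: float = 0.0,
    S1: float = 1.0,
    noise: float = 0.02,
    seed: int = 0,
    buffered: bool = False,
    chelator_total: float = 1e-3,
    K_cond: float = 1e7,
) -> tuple[TitrationDataset, dict]:
    """A Hill-response titration sampled log-uniformly in free metal.

    The span defaults to ``span_decades`` centred on K_d.  Noise is
    multiplicative Gaussian on the signal.  With ``buffered`` set, each
    point also gets the 1:1 chelator-buffer composition (total metal,
    chelator, conditional constant) that produces exactly that free metal
    concentration, so the buffered fitting path can be exercised against
    the speciation solver.
    """
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    if span is None:
        half = span_decades / 2.0
        span = (K_d * 10.0**-half, K_d * 10.0**half)
    x = np.geomspace(span[0], span[1], n_points)
    rng = _rng(seed, "titration")
    y_true = hill_signal(x, K_d, hill_n, S0, S1)
    y = y_true * (1.0 + noise * rng.standard_normal(n_points)) if noise > 0 else y_true.copy()
    buffers = None
    if buffered:
        buffers = []
        for xi in x:
            complex_conc = K_cond * xi * chelator_total / (1.0 + K_cond * xi)
            buffers.append(
                BufferSystem(
                    total_metal=xi + complex_conc,
                    total_chelator=chelator_total,
                    K_cond=K_cond,
                )
            )
        # closure check: forward solver must reproduce the free-metal axis
        back = np.array([free_metal(b) for b in buffers])
        assert np.allclose(back, x, rtol=1e-8)
    data = TitrationDataset(
        conc=np.array([b.total_metal for b in buffers]) if buffered else x,
        signal=y,
        buffered=buffered,
        buffers=buffers,
    )
    truth = {
        "seed": seed, "K_d": K_d, "hill_n": hill_n, "S0": S0, "S1": S1,
        "noise": noise, "free_metal": x.tolist(), "buffered": buffered,
    }
    return data, truth


def gen_itc(
    K_dimer: float,
    dH_diss: float,
    *,
    syringe_conc: float = 300e-6,
    cell_volume: float = 185e-6,
    injections: list[float] | None = None,
    temperature: float = 303.15,
    q_blank: float = 0.0,
    noise: float = 0.02,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> tuple[ITCExperiment, dict]:
    """Dilution-ITC heats from the dimer-dissociation forward model.

    Defaults reproduce the standard schedule: one 0.2 µl pre-injection plus
    17 x 2 µl into a 185 µl cell from a 300 µM syringe at 30 C.  Noise is
    multiplicative Gaussian, optionally plus an additive instrument floor
    (J per injection; ~0.1 µJ is typical of low-volume calorimeters).  With
    a floor enabled, a tight dimer's heats disappear into it - exactly the
    physical insensitivity the fit must flag as bound-only.
    """
    exp = ITCExperiment(
        syringe_conc=syringe_conc,
        cell_volume=cell_volume,
        injections=injections or default_injection_schedule(),
        temperature=temperature,
        K_dimer=K_dimer,
        dH_diss=dH_diss,
        q_blank=q_blank,
    )
    heats = itc_forward(exp)
    rng = _rng(seed, "itc")
    if noise > 0 or noise_floor > 0:
        heats = heats * (1.0 + noise * rng.standard_normal(len(heats)))
        heats = heats + noise_floor * rng.standard_normal(len(heats))
    exp.heats = heats
    truth = {
        "seed": seed, "K_dimer": K_dimer, "dH_diss": dH_diss, "q_blank": q_blank,
        "noise": noise, "noise_floor": noise_floor,
    }
    return exp, truth


def gen_decay_series(
    tau_H2O_ms: float = 0.5,
    slope_m: float = -0.334,
    *,
    fractions: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75),
    n_time: int = 250,
    span_us: float = 2500.0,
    peak_counts: float = 5000.0,
    baseline_counts: float = 0.0,
    noise: float = 0.01,
    noise_model: str = "relative",
    seed: int = 0,
) -> tuple[list[DecayTrace], SolventSeries, dict]:
    """Luminescence decays whose rate varies linearly with D2O fraction.

    Per-fraction lifetimes follow 1/tau(f) = 1/tau_H2O + m*f (ms^-1); each
    trace is a single exponential over the measurement window.  ``noise``
    is relative Gaussian ("relative") or Poisson counting noise ("poisson").
    The returned SolventSeries holds the *true* lifetimes; fitting the
    traces and regressing recovers them within the noise.
    """
    fracs = np.asarray(fractions, dtype=float)
    rates = 1.0 / tau_H2O_ms + slope_m * fracs  # ms^-1
    if np.any(rates <= 0):
        raise ValueError("slope/fraction combination gives non-positive decay rates")
    taus_ms = 1.0 / rates
    t_us = np.linspace(0.0, span_us, n_time)
    rng = _rng(seed, "decays")
    traces = []
    for tau_ms in taus_ms:
        ideal = peak_counts * np.exp(-t_us / (tau_ms * 1000.0)) + baseline_counts
        if noise_model == "poisson" and noise > 0:
            y = rng.poisson(ideal).astype(float)
        elif noise > 0:
            y = ideal * (1.0 + noise * rng.standard_normal(n_time))
        else:
            y = ideal.copy()
        traces.append(DecayTrace(time_us=t_us.copy(), intensity=np.clip(y, 0, None),
                                 span_us=span_us))
    # single-fraction runs (one trace) carry no regressable series
    series = (
        SolventSeries(d2o_fraction=fracs, tau_ms=taus_ms) if len(fracs) >= 2 else None
    )
    truth = {
        "seed": seed, "tau_H2O_ms": tau_H2O_ms, "slope_m": slope_m,
        "tau_ms": taus_ms.tolist(), "noise": noise, "noise_model": noise_model,
    }
    return traces, series, truth


def gen_elution(
    *,
    metals: dict[str, dict] | None = None,
    bed_volumes: np.ndarray | None = None,
    bed_volume_ml: float = 0.7,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[SeparationTable, dict]:
    """Two-metal (or more) Gaussian elution profiles with exact mass closure.

    ``metals`` maps metal -> {"amount": mol loaded, "center": BV, "width": BV};
    the default emulates a 95:5 Nd/Dy feed where the Dy peak elutes first
    under the selective chelator steps and Nd follows in the acid strip.
    Discrete per-fraction concentrations are normalized so that the summed
    moles (concentration x fraction volume) equal the loaded amount exactly,
    giving closed purity/yield arithmetic.
    """
    if metals is None:
        # 95:5 Nd:Dy on a 1 ml-scale load (moles); disjoint-ish peaks
        metals = {
            "Dy": {"amount": 0.05e-6 * 20, "center": 6.0, "width": 1.2},
            "Nd": {"amount": 0.95e-6 * 20, "center": 16.0, "width": 1.2},
        }
    if bed_volumes is None:
        bed_volumes = np.arange(0.5, 25.0 + 1e-9, 0.5)
    bv = np.asarray(bed_volumes, dtype=float)
    vol_l = np.diff(bv, prepend=0.0) * bed_volume_ml * 1e-3
    rng = _rng(seed, "elution")
    import pandas as pd

    cols = {"bed_volume": bv}
    for metal, p in metals.items():
        shape = np.exp(-0.5 * ((bv - p["center"]) / p["width"]) ** 2)
        if noise > 0:
            shape = shape * (1.0 + noise * rng.standard_normal(len(bv)))
            shape = np.clip(shape, 0.0, None)
        weights = shape * vol_l
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"{metal}: elution profile sums to zero")
        conc = p["amount"] * shape / total  # mol/L per fraction
        cols[metal] = conc
    table = SeparationTable(
        fractions=pd.DataFrame(cols), bed_volume_ml=bed_volume_ml,
        metals=list(metals),
    )
    truth = {"seed": seed, "metals": metals, "noise": noise,
             "bed_volume_ml": bed_volume_ml}
    return table, truth


def _unit_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def gen_metal_site(
    *,
    element: str = "LA",
    cn: int = 10,
    shell_radius: float = 2.5,
    radius_jitter: float = 0.05,
    denticity_plan: tuple[str, ...] = ("bidentate", "bidentate"),
    n_decoys: int = 2,
    decoy_radius: float = 3.6,
    chain_name: str = "A",
    seed: int = 0,
):
    """An idealized metal coordination site as a gemmi structure + truth.

    Places ``cn`` donor oxygens on a jittered sphere of ``shell_radius``
    around a single metal ion.  Carboxylate residues (Glu) consume two
    donor slots when bidentate and one when monodentate (their second
    oxygen then sits at ``decoy_radius``, outside the default cutoff);
    remaining slots are filled with water oxygens.  ``n_decoys`` extra
    oxygens beyond the cutoff must never be counted.  The structure writes
    as a valid minimal PDB (synthetic - not derived from any deposition).
    """
    import gemmi

    slots_needed = sum(2 if m == "bidentate" else 1 for m in denticity_plan)
    if slots_needed > cn:
        raise ValueError("denticity plan needs more donor slots than the coordination number")
    n_waters = cn - slots_needed
    rng = _rng(seed, "metal_site")
    n_dirs = len(denticity_plan) + n_waters + n_decoys
    dirs = _unit_sphere(max(n_dirs, 2))

    st = gemmi.Structure()
    st.name = "synthetic_metal_site"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_name)

    def add_residue(name: str, seqid: int, atoms: list[tuple[str, str, np.ndarray]]):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        res.het_flag = "H"
        for aname, elem, xyz in atoms:
            a = gemmi.Atom()
            a.name = aname
            a.element = gemmi.Element(elem)
            a.pos = gemmi.Position(*map(float, xyz))
            a.occ = 1.0
            res.add_atom(a)
        chain.add_residue(res)

    add_residue(element, 200, [(element, element.capitalize(), np.zeros(3))])

    truth_calls = []
    d_idx = 0
    seqid = 10
    for mode in denticity_plan:
        u = dirs[d_idx]
        d_idx += 1
        r1 = shell_radius + rng.normal(0.0, radius_jitter)
        o1 = r1 * u
        # perpendicular direction for the partner oxygen
        v = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(v) < 1e-6:
            v = np.cross(u, [0.0, 1.0, 0.0])
        v /= np.linalg.norm(v)
        if mode == "bidentate":
            r2 = shell_radius + rng.normal(0.0, radius_jitter)
            alpha = 2.0 * np.arcsin(min(1.1 / r2, 1.0))  # O-O chord ~2.2 A
            o2 = r2 * (np.cos(alpha) * u + np.sin(alpha) * v)
        else:
            o2 = decoy_radius * (np.cos(0.4) * u + np.sin(0.4) * v)
        add_residue("GLU", seqid, [("OE1", "O", o1), ("OE2", "O", o2)])
        truth_calls.append({"res_seq": seqid, "mode": mode})
        seqid += 1
    for w in range(n_waters):
        u = dirs[d_idx]
        d_idx += 1
        r = shell_radius + rng.normal(0.0, radius_jitter)
        add_residue("HOH", 300 + w, [("O", "O", r * u)])
    for k in range(n_decoys):
        u = dirs[d_idx % len(dirs)]
        d_idx += 1
        r = decoy_radius + rng.uniform(0.0, 0.5)
        add_residue("HOH", 400 + k, [("O", "O", r * u)])

    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    truth = {
        "seed": seed,
        "element": element,
        "cn": cn,
        "metal_res_seq": 200,
        "denticity": truth_calls,
        "n_waters_in_shell": n_waters,
        "n_decoys": n_decoys,
    }
    return st, truth
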