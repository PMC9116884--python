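"""Self-contained end-to-end walkthrough on synthetic data.

Generates a two-locus F2 cross, extreme-pool sequencing, a duplicated-region
coverage profile, junction sequences, a sweep-bearing site sample and a
selection trajectory, runs every pipeline stage and asserts five checks:

1. the bulk-segregant scan recovers both causal loci (one high region, one
   low region, each containing its locus);
2. the copy-number estimator recovers the simulated copy number;
3. junction classification inverts the junction generator for all three
   mechanisms;
4. the CLR scan's peak localizes within one grid step of the simulated
   sweep site;
5. the selection-coefficient fit recovers the simulated s.
"""

from __future__ import annotations

import json

import numpy as np

from . import bsa as bsa_mod
from . import cnv as cnv_mod
from . import popgen, simulate
from .config import PipelineConfig

__all__ = ["run_demo"]


def _check_bsa(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    sim = cfg.simulate
    marker_map = simulate.default_marker_map(
        sim.n_chromosomes, sim.chrom_length, sim.markers_per_chrom
    )
    locus_a = ("4", sim.chrom_length // 2)
    locus_b = ("1", sim.chrom_length // 2)
    snap = lambda locus: min(
        (m for m in marker_map if m[0] == locus[0]), key=lambda m: abs(m[1] - locus[1])
    )
    locus_a, locus_b = snap(locus_a), snap(locus_b)
    cross = simulate.CrossConfig(
        n_individuals=sim.n_individuals,
        locus_a=locus_a,
        locus_b=locus_b,
        marker_map=marker_map,
        seed=int(rng.integers(2**31)),
    )
    cohort = simulate.simulate_f2_cross(cross)
    pool = simulate.select_extreme_pool(cohort.phenotype, cfg.simulate.pool_size)
    counts = simulate.simulate_pool_reads(
        cohort, pool, mean_depth=sim.pool_depth, seed=int(rng.integers(2**31))
    )
    freqs = bsa_mod.pool_frequency(counts, min_depth=cfg.bsa.min_depth)
    track = bsa_mod.window_scan(
        freqs, counts.pos, counts.chrom, cfg.bsa.window_bp, cfg.bsa.step_bp
    )
    peaks = bsa_mod.call_peaks(track, cfg.bsa.high, cfg.bsa.low)
    hit_low = any(
        p.direction == "low" and p.chrom == locus_a[0] and p.start <= locus_a[1] < p.end
        for p in peaks
    )
    hit_high = any(
        p.direction == "high" and p.chrom == locus_b[0] and p.start <= locus_b[1] < p.end
        for p in peaks
    )
    return {
        "check": "bsa_locus_recovery",
        "pass": bool(hit_low and hit_high),
        "detail": f"{len(peaks)} regions; locus_a in low region: {hit_low}; locus_b in high region: {hit_high}",
    }


def _check_cnv(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    true_cn = 3
    spec = simulate.CoverageSimSpec(
        region_length=60_000,
        base_depth=40.0,
        cn_track=[(22_501, 37_501, true_cn)],
        zygosity="homozygous",
        seed=int(rng.integers(2**31)),
    )
    profile = simulate.simulate_coverage(spec)
    est = cnv_mod.normalized_coverage(
        profile, (22_501, 37_501), cfg.cnv.window, cfg.cnv.step, cfg.cnv.flank
    )
    return {
        "check": "cn_recovery",
        "pass": est.integer_cn == true_cn,
        "detail": f"median ratio {est.median_ratio:.3f}, integer CN {est.integer_cn} (truth {true_cn})",
    }


def _check_junctions(rng: np.random.Generator) -> dict:
    bases = np.array(list("ACGT"))
    ok = True
    details = []
    for mech in (
        simulate.Microhomology("CT"),
        simulate.Templated("AAGACATAA"),
        simulate.Blunt(),
    ):
        ref = "".join(rng.choice(bases, size=600))
        spec = simulate.JunctionSpec(ref, (200, 400), mech)
        result = simulate.make_duplication_junction(spec, seed=int(rng.integers(2**31)))
        e, s = 400, 200
        probe = 25
        ins = len(result.annotation.signature) if result.annotation.mechanism == "templated" else 0
        observed = result.derived[e - probe : e + ins + probe]
        call = cnv_mod.classify_junction(result.reference, e, s, observed)
        same = (
            call.mechanism == result.annotation.mechanism
            and call.signature == result.annotation.signature
        )
        ok &= same
        details.append(f"{result.annotation.mechanism}->{call.mechanism}")
    return {"check": "junction_roundtrip", "pass": bool(ok), "detail": ", ".join(details)}


def _check_clr(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    n = 10
    bg = popgen.BackgroundSpectrum.from_polymorphic(1.0 / np.arange(1, n))
    span = 2_000_000
    center = span // 2
    positions = np.sort(rng.choice(np.arange(1, span), size=1_200, replace=False))
    freq = simulate.conditioned_sweep_trajectory(
        N=5_000, s=0.1, h=0.5, seed=int(rng.integers(2**31))
    )
    derived = _sample_sweep_sites(bg, positions, center, freq, n, 1e-8, rng)
    track = popgen.clr_scan(positions, derived, n, bg, grid_bp=cfg.popgen.grid_bp)
    peak = int(track.grid[np.argmax(track.clr)])
    ok = abs(peak - center) <= cfg.popgen.grid_bp
    return {
        "check": "clr_localization",
        "pass": bool(ok),
        "detail": f"peak at {peak}, sweep at {center}, grid {cfg.popgen.grid_bp}",
    }


def _sample_sweep_sites(
    bg: popgen.BackgroundSpectrum,
    positions: np.ndarray,
    center: int,
    sweep_freq: np.ndarray,
    n: int,
    r_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw derived counts near a completed hard sweep.

    The escape probability of each lineage integrates recombination off the
    sweeping background over the simulated frequency trajectory:
    ``P_e(d) = 1 - exp(-r d integral(1 - p_t) dt)``. Escaped lineages sample
    the background spectrum; the swept ancestor's allele is drawn from the
    same pre-sweep sample. Sites are redrawn until polymorphic.
    """
    exposure = float(np.sum(1.0 - sweep_freq))
    p_esc = -np.expm1(-r_per_bp * np.abs(positions - center) * exposure)
    classes = np.arange(1, bg.n)
    probs = bg.probs[1:-1]
    derived = np.empty(len(positions), dtype=np.int64)
    for i, pe in enumerate(p_esc):
        while True:
            esc = rng.random(n) < pe
            e = int(esc.sum())
            m = e + 1 if e < n else n
            j_full = int(rng.choice(classes, p=probs))  # derived among bg.n
            # hypergeometric downsample of the background draw to m lineages
            j = int(rng.hypergeometric(j_full, bg.n - j_full, m))
            if e < n:
                if rng.random() < j / m:
                    b = (n - e) + (j - 1)
                else:
                    b = j
            else:
                b = j
            if 0 < b < n:
                derived[i] = b
                break
    return derived


def _check_selection(rng: np.random.Generator) -> dict:
    s_true, h = 0.1, 0.5
    traj = popgen.wright_fisher_deterministic(0.01, s_true, h, 200)
    fit = popgen.estimate_s(0.01, float(traj[-1]), 200, h)
    ok = abs(fit.s_hat - s_true) < 1e-4
    return {
        "check": "selection_recovery",
        "pass": bool(ok),
        "detail": f"s_hat {fit.s_hat:.6f} (truth {s_true})",
    }


def run_demo(cfg: PipelineConfig | None = None, report_path: str | None = None) -> list[dict]:
    """Run all five stage checks; raises RuntimeError naming the first failure."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    report = [
        _check_bsa(cfg, rng),
        _check_cnv(cfg, rng),
        _check_junctions(rng),
        _check_clr(cfg, rng),
        _check_selection(rng),
    ]
    if report_path:
        with open(report_path, "w") as fh:
            json.dump({"seed": cfg.seed, "checks": report}, fh, indent=2)
            fh.write("\n")
    failures = [r["check"] for r in report if not r["pass"]]
    if failures:
        raise RuntimeError(f"demo stage(s) failed: {', '.join(failures)}")
    return report
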