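"""FDTD engine physics: propagation, boundaries, stability, determinism."""

import numpy as np
import pytest
from scipy.signal import hilbert

from octfdtd import (
    C,
    FDTDInstabilityError,
    FieldState,
    GridSpec,
    MaterialMap,
    SourceSpec,
    Solver,
    attach_absorbing_boundary,
    fresnel_transmission,
    run_simulation,
    source_amplitude,
    step_fields,
)
from octfdtd.boundary import PMLSpec

LAMBDA0 = 850e-9


def quasi_1d(dx, extent_x, extent_y=0.3e-6, n=1.0):
    grid = GridSpec.create(dx, extent_x, extent_y)
    return grid, MaterialMap.uniform(grid, n)


def envelope_peak_time(trace):
    env = np.abs(hilbert(trace.amplitudes))
    k = int(np.argmax(env))
    # quadratic interpolation around the peak for sub-sample timing
    if 0 < k < env.size - 1:
        a, b, c = env[k - 1], env[k], env[k + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        return trace.times[k] + shift * trace.dt
    return trace.times[k]


class TestStepFields:
    def test_zero_fields_stay_zero(self):
        grid, mat = quasi_1d(LAMBDA0 / 25, 2e-6)
        state = FieldState(
            np.zeros(grid.shape), np.zeros((grid.n_cells_x, grid.n_cells_y - 1)),
            np.zeros((grid.n_cells_x - 1, grid.n_cells_y)),
        )
        out = state
        for _ in range(5):
            out = step_fields(out, mat, grid)
        assert not np.any(out.E)
        assert not np.any(out.H1)
        assert not np.any(out.H2)
        assert out.time_index == 5

    def test_material_shape_mismatch_rejected(self):
        grid, _ = quasi_1d(LAMBDA0 / 25, 2e-6)
        other = MaterialMap.uniform(GridSpec.create(LAMBDA0 / 25, 1e-6, 0.3e-6), 1.0)
        state = FieldState(
            np.zeros(grid.shape), np.zeros((grid.n_cells_x, grid.n_cells_y - 1)),
            np.zeros((grid.n_cells_x - 1, grid.n_cells_y)),
        )
        with pytest.raises(ValueError):
            step_fields(state, other, grid)

    def test_instability_signalled_with_step_index(self):
        grid, mat = quasi_1d(LAMBDA0 / 25, 2e-6)
        solver = Solver(grid, mat, check_finite_every=1)
        solver.E[5, 5] = np.nan
        with pytest.raises(FDTDInstabilityError) as err:
            solver.step()
        assert err.value.step == 1


class TestPropagation:
    def test_vacuum_pulse_travels_at_c(self):
        """Envelope peak delay between two probes matches d/c within 1%."""
        dx = LAMBDA0 / 100
        grid, mat = quasi_1d(dx, 12e-6)
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=1.5e-6)
        res = run_simulation(
            grid, mat, src, [(3e-6, 0.15e-6), (9e-6, 0.15e-6)], 3500,
            periodic_y=True, subsample_every=1,
        )
        t1 = envelope_peak_time(res.traces[0])
        t2 = envelope_peak_time(res.traces[1])
        expected = 6e-6 / C
        assert (t2 - t1) == pytest.approx(expected, rel=0.01)

    def test_numerical_dispersion_shrinks_with_resolution(self):
        """Arrival-time error decreases from 20 to 100 cells per wavelength."""
        errors = {}
        for cells in (20, 100):
            dx = LAMBDA0 / cells
            grid, mat = quasi_1d(dx, 12e-6)
            src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=1.5e-6)
            n_steps = int(3500 * (100 / cells) / 5) * 5
            res = run_simulation(
                grid, mat, src, [(3e-6, 0.15e-6), (9e-6, 0.15e-6)], n_steps,
                periodic_y=True, subsample_every=1,
            )
            delay = envelope_peak_time(res.traces[1]) - envelope_peak_time(res.traces[0])
            errors[cells] = abs(delay - 6e-6 / C)
        assert errors[100] < errors[20]

    def test_probe_at_source_reproduces_pulse_shape(self):
        """Normalised probe waveform matches the source waveform."""
        dx = LAMBDA0 / 50
        grid, mat = quasi_1d(dx, 10e-6)
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=2e-6)
        res = run_simulation(grid, mat, src, [(4e-6, 0.15e-6)], 2500,
                             periodic_y=True, subsample_every=1)
        tr = res.traces[0]
        delay = 2e-6 / C
        model = source_amplitude(src, tr.times - delay)
        a = tr.amplitudes / np.max(np.abs(tr.amplitudes))
        b = model / np.max(np.abs(model))
        # correlation-based shape comparison tolerating residual dispersion
        corr = np.max(np.correlate(a, b, "full")) / (
            np.linalg.norm(a) * np.linalg.norm(b)
        )
        assert corr > 0.99

    def test_mirror_echo_delay(self):
        """Round trip to a perfect mirror at distance d returns after 2d/c."""
        dx = LAMBDA0 / 50
        grid, mat = quasi_1d(dx, 15e-6)
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=1.5e-6)
        res = run_simulation(grid, mat, src, [(3e-6, 0.15e-6)], 8000,
                             periodic_y=True, mirror_x=10e-6, subsample_every=10)
        tr = res.traces[0]
        env = np.abs(hilbert(tr.amplitudes))
        import scipy.signal as ss

        peaks, _ = ss.find_peaks(env, height=0.1 * env.max(), distance=50)
        assert peaks.size >= 2
        echo_delay = tr.times[peaks[1]] - tr.times[peaks[0]]
        assert echo_delay == pytest.approx(2 * 7e-6 / C, abs=tr.dt)

    def test_fresnel_interface_intensity_transmission(self):
        """Plane pulse across water->glass transmits ~0.9959 in intensity."""
        n1, n2 = 1.3272, 1.5098
        dx = LAMBDA0 / 100
        grid = GridSpec.create(dx, 16e-6, 0.3e-6)
        x = np.arange(grid.n_cells_x) * dx
        n = np.where(x < 8e-6, n1, n2)
        mat = MaterialMap(
            np.repeat(n[:, None], grid.n_cells_y, 1),
            np.repeat((x >= 8e-6).astype(np.int16)[:, None], grid.n_cells_y, 1),
            {0: "water", 1: "glass"}, {"water": n1, "glass": n2},
        )
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=1.5e-6)
        res = run_simulation(grid, mat, src, [(4e-6, 0.15e-6), (12e-6, 0.15e-6)],
                             9000, periodic_y=True, subsample_every=1)
        inc, trans = res.traces
        t_cut = src.t0 + (2.5e-6 + 2 * 4e-6) * n1 / C  # before the echo returns
        gated = inc.windowed(0.0, t_cut)
        e_i = np.max(np.abs(hilbert(gated.amplitudes)))
        e_t = np.max(np.abs(hilbert(trans.amplitudes)))
        T = (n2 / n1) * (e_t / e_i) ** 2
        assert T == pytest.approx(fresnel_transmission(n1, n2), rel=0.01)


class TestDeterminismAndStability:
    def test_identical_runs_bit_identical(self):
        dx = LAMBDA0 / 30
        grid, mat = quasi_1d(dx, 6e-6, n=1.33)
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=1.5e-6)
        runs = [
            run_simulation(grid, mat, src, [(3e-6, 0.15e-6)], 1500, periodic_y=True)
            for _ in range(2)
        ]
        a, b = runs[0].traces[0], runs[1].traces[0]
        assert np.array_equal(a.amplitudes, b.amplitudes)
        assert np.array_equal(a.times, b.times)

    def test_long_run_remains_finite_at_courant_limit(self):
        """1e5 steps on a 200x200 grid with n >= 1 material stay finite."""
        dx = LAMBDA0 / 25
        grid = GridSpec.create(dx, 200 * dx, 200 * dx)
        x = np.arange(200) * dx
        n = np.where(x[:, None] + 0 * x[None, :] < 100 * dx, 1.0, 1.5)
        mat = MaterialMap(n, (n > 1).astype(np.int16), {0: "a", 1: "b"},
                          {"a": 1.0, "b": 1.5})
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15,
                         x=60 * dx, y=100 * dx, injection_mode="point")
        res = run_simulation(grid, mat, src, [(60 * dx, 100 * dx)], 100_000,
                             subsample_every=1000)
        assert np.all(np.isfinite(res.traces[0].amplitudes))

    def test_rejects_nonpositive_steps(self):
        grid, mat = quasi_1d(LAMBDA0 / 25, 2e-6)
        with pytest.raises(ValueError):
            run_simulation(grid, mat, None, [], 0)

    def test_probe_inside_pml_rejected(self):
        grid, mat = quasi_1d(LAMBDA0 / 25, 4e-6, 2e-6)
        with pytest.raises(ValueError):
            run_simulation(grid, mat, None, [(1e-7, 1e-6)], 10)


class TestAbsorbingBoundary:
    def run_against_oracle(self, target_reflection, n_steps=2500):
        # 2500 steps: the short domain's PML reflection reaches the probe,
        # the doubled domain's far-edge reflection has not yet returned
        """Reflected energy from the right PML vs a domain twice as long."""
        dx = LAMBDA0 / 40
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=2e-6)
        traces = []
        for extent in (10e-6, 25e-6):
            grid, mat = quasi_1d(dx, extent)
            res = run_simulation(
                grid, mat, src, [(3e-6, 0.15e-6)], n_steps,
                pml_spec=PMLSpec(10, 3, target_reflection),
                periodic_y=True, subsample_every=1,
            )
            traces.append(res.traces[0])
        short, long_ = traces
        d = short.amplitudes - long_.amplitudes
        return float(np.sum(d**2) / np.sum(long_.amplitudes**2))

    def test_reflected_energy_below_1e4(self):
        assert self.run_against_oracle(1e-6) < 1e-4

    def test_lower_target_never_worsens_reflection(self):
        """Grading monotonicity, measured above the discretisation floor."""
        r = [self.run_against_oracle(t) for t in (1e-1, 1e-2, 1e-4)]
        assert r[1] <= r[0]
        assert r[2] <= r[1]

    def test_pulse_fully_absorbed_late_time_energy(self):
        dx = LAMBDA0 / 40
        grid, mat = quasi_1d(dx, 10e-6)
        src = SourceSpec(lambda0=LAMBDA0, pulse_length=25e-15, x=3e-6)
        pml = attach_absorbing_boundary(grid, 10, 3, 1e-6, axes=("x",))
        solver = Solver(grid, mat, pml=pml, periodic_y=True, source=src)
        peak = 0.0
        for _ in range(6000):
            solver.step()
            if solver.time_index % 50 == 0:
                peak = max(peak, solver.total_energy())
        # stop feeding the source and let the tail drain
        solver.source = None
        for _ in range(4000):
            solver.step()
        assert solver.total_energy() < 1e-6 * peak

    def test_thickness_exceeding_half_domain_rejected(self):
        grid, _ = quasi_1d(LAMBDA0 / 25, 2e-6, 2e-6)
        with pytest.raises(ValueError):
            attach_absorbing_boundary(grid, grid.n_cells_x // 2 + 1)

    def test_thin_pml_rejected(self):
        grid, _ = quasi_1d(LAMBDA0 / 25, 2e-6, 2e-6)
        with pytest.raises(ValueError):
            attach_absorbing_boundary(grid, 3)
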