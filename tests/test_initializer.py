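"""Strategy-to-subject mapping, trajectory pairing, 2-sigma validation."""

import itertools

import numpy as np
import pytest

from seegplan import (
    AffineTransform,
    CohortSpec,
    Descriptor,
    MeanTrajectory,
    ModelBundle,
    Plan,
    Point3,
    Strategy,
    Trajectory,
    build_model_bundle,
    generate_atlas,
    generate_cohort,
    init_plan,
    match_trajectories,
    validate_mapping,
)
from seegplan.initializer import PairedTrajectories


def _mt(y, entry, target, sigma=2.0, n_members=5, desc=None):
    return MeanTrajectory(
        descriptor=desc or Descriptor(1, 2), index_u=1,
        mean_entry=Point3(*entry), mean_target=Point3(*target),
        sigma_entry=sigma, sigma_target=sigma, n_members=n_members,
        member_refs=[("p0", f"E{y}")],
    )


def _bundle(mts, strategy_bits=None):
    strategies = []
    if strategy_bits is not None:
        strategies = [Strategy("S1", strategy_bits)]
    return ModelBundle(mean_trajectories=mts, strategies=strategies)


class TestInitPlan:
    def test_identity_affine_preserves_coordinates(self):
        bundle = _bundle([_mt(1, (10, 0, 80), (10, 0, 20))], [True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        (y, tr) = ip.entries[0]
        assert y == 1 and tr.space == "subject"
        assert tr.entry == Point3(10, 0, 80)
        assert tr.electrode_id == "mT1"

    def test_translation_affine_applies_inverse(self):
        m = np.eye(4)
        m[:3, 3] = [5, -3, 7]  # subject -> average translation
        bundle = _bundle([_mt(1, (10, 0, 80), (10, 0, 20))], [True])
        ip = init_plan(bundle, "S1", AffineTransform(m))
        (_, tr) = ip.entries[0]
        assert tr.entry == Point3(5, 3, 73)
        assert tr.target == Point3(5, 3, 13)

    def test_all_false_strategy_gives_empty_plan(self):
        bundle = _bundle([_mt(1, (0, 0, 80), (0, 0, 20))], [False])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        assert ip.entries == []

    def test_unknown_strategy_raises(self):
        bundle = _bundle([_mt(1, (0, 0, 80), (0, 0, 20))], [True])
        with pytest.raises(KeyError):
            init_plan(bundle, "NOPE", AffineTransform.identity())


def _manual(trajs):
    return Plan(plan_id="mp", patient_id="pat", trajectories=trajs)


def _subject_tr(eid, entry, target):
    return Trajectory("mp", eid, Point3(*entry), Point3(*target), space="subject")


def brute_force_min_cost(cost):
    """Exhaustive assignment oracle over all permutations (square cost)."""
    n = cost.shape[0]
    return min(sum(cost[i, p[i]] for i in range(n))
               for p in itertools.permutations(range(n)))


class TestMatchTrajectories:
    def test_forced_single_pair(self):
        bundle = _bundle([_mt(1, (0, 0, 80), (0, 0, 20))], [True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        manual = _manual([_subject_tr("M1", (1, 0, 80), (1, 0, 20))])
        pairing = match_trajectories(ip, manual, bundle)
        assert len(pairing.pairs) == 1
        assert pairing.pairs[0][0] == 1 and pairing.pairs[0][1] == "M1"
        assert pairing.unpaired_manual == [] and pairing.unpaired_initialized == []

    def test_assignment_beats_greedy_nearest(self):
        """Greedy nearest-entry pairing is suboptimal here; the assignment
        swaps and its total equals the brute-force permutation minimum."""
        bundle = _bundle([
            _mt(1, (0, 0, 80), (0, 0, 20)),
            _mt(2, (5, 0, 80), (5, 0, 20)),
        ], [True, True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        manual = _manual([
            _subject_tr("M1", (1, 0, 80), (1, 0, 20)),   # nearest to IP1
            _subject_tr("M2", (-2, 0, 80), (-2, 0, 20)),
        ])
        pairing = match_trajectories(ip, manual, bundle)
        got = {(y, mid) for y, mid, _, _ in pairing.pairs}
        assert got == {(1, "M2"), (2, "M1")}
        cost = np.zeros((2, 2))
        for i, (_, ip_tr) in enumerate(ip.entries):
            for j, mp_tr in enumerate(manual.trajectories):
                cost[i, j] = (ip_tr.entry.distance_to(mp_tr.entry)
                              + ip_tr.target.distance_to(mp_tr.target))
        total = sum(cost[{1: 0, 2: 1}[y], {"M1": 0, "M2": 1}[mid]]
                    for y, mid, _, _ in pairing.pairs)
        assert total == pytest.approx(brute_force_min_cost(cost))

    def test_surplus_initialized_left_unpaired(self):
        bundle = _bundle([
            _mt(1, (0, 0, 80), (0, 0, 20)),
            _mt(2, (20, 0, 80), (20, 0, 20)),
            _mt(3, (40, 0, 80), (40, 0, 20)),
        ], [True, True, True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        manual = _manual([
            _subject_tr("M1", (0, 1, 80), (0, 1, 20)),
            _subject_tr("M2", (40, 1, 80), (40, 1, 20)),
        ])
        pairing = match_trajectories(ip, manual, bundle)
        assert len(pairing.pairs) == 2
        assert pairing.unpaired_initialized == [2]
        assert pairing.unpaired_manual == []

    def test_descriptor_constraint_forbids_cross_pattern_pairs(self):
        dA, dB = Descriptor(1, 2), Descriptor(3, 4)
        bundle = _bundle([
            _mt(1, (0, 0, 80), (0, 0, 20), desc=dA),
            _mt(2, (10, 0, 80), (10, 0, 20), desc=dB),
        ], [True, True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        # geometrically swapped, but descriptors force the crossed pairing
        manual = _manual([
            _subject_tr("M1", (10, 0, 80), (10, 0, 20)),
            _subject_tr("M2", (0, 0, 80), (0, 0, 20)),
        ])
        pairing = match_trajectories(ip, manual, bundle,
                                     manual_descriptors={"M1": dA, "M2": dB})
        got = {(y, mid) for y, mid, _, _ in pairing.pairs}
        assert got == {(1, "M1"), (2, "M2")}


class TestValidateMapping:
    def test_exact_mapping_passes_with_zero_distances(self):
        bundle = _bundle([_mt(1, (0, 0, 80), (0, 0, 20))], [True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        manual = _manual([_subject_tr("M1", (0, 0, 80), (0, 0, 20))])
        report = validate_mapping(match_trajectories(ip, manual, bundle), bundle)
        assert report.fraction_mapped == 1.0
        assert report.pairs[0].d_ep == 0.0 and report.pairs[0].d_tp == 0.0

    def test_boundary_two_sigma_is_inclusive(self):
        bundle = _bundle([_mt(1, (0, 0, 80), (0, 0, 20), sigma=2.0)], [True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        manual = _manual([_subject_tr("M1", (4, 0, 80), (4, 0, 20))])  # d = 2*sigma
        report = validate_mapping(match_trajectories(ip, manual, bundle), bundle)
        assert report.pairs[0].d_ep == pytest.approx(4.0)
        assert report.pairs[0].passed

    def test_just_beyond_two_sigma_fails(self):
        bundle = _bundle([_mt(1, (0, 0, 80), (0, 0, 20), sigma=2.0)], [True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        manual = _manual([_subject_tr("M1", (4.01, 0, 80), (4.01, 0, 20))])
        report = validate_mapping(match_trajectories(ip, manual, bundle), bundle)
        assert not report.pairs[0].passed

    def test_singleton_sigma_zero_autofails_unless_exact(self):
        bundle = _bundle([_mt(1, (0, 0, 80), (0, 0, 20), sigma=0.0, n_members=1)],
                         [True])
        ip = init_plan(bundle, "S1", AffineTransform.identity())
        near = _manual([_subject_tr("M1", (0.001, 0, 80), (0.001, 0, 20))])
        report = validate_mapping(match_trajectories(ip, near, bundle), bundle)
        assert not report.pairs[0].passed and report.pairs[0].degenerate_sigma
        exact = _manual([_subject_tr("M1", (0, 0, 80), (0, 0, 20))])
        report = validate_mapping(match_trajectories(ip, exact, bundle), bundle)
        assert report.pairs[0].passed

    def test_empty_pairing_reports_zero_fraction(self):
        report = validate_mapping(PairedTrajectories(pairs=[]), _bundle(
            [_mt(1, (0, 0, 80), (0, 0, 20))], [True]))
        assert report.fraction_mapped == 0.0


def test_noisy_test_subjects_fraction_matches_monte_carlo_oracle():
    """On test subjects drawn from the planted model with training-level
    noise, the fraction passing the 2-sigma rule matches a direct Monte-Carlo
    simulation of the noise model."""
    spec = CohortSpec(seed=31, n_strategies=2, mts_per_strategy=3, n_plans=30,
                      plan_dropout_prob=0.0)
    volume, cfg = generate_atlas(spec)
    plans, affines, truth = generate_cohort(spec)
    bundle = build_model_bundle(plans, affines, volume, cfg, seed=spec.seed)
    from seegplan.pipeline import add_strategies
    add_strategies(bundle, cut_threshold=0.7)

    # fresh test subjects from the same generative process
    test_spec = CohortSpec(seed=77, n_strategies=2, mts_per_strategy=3,
                           n_plans=40, plan_dropout_prob=0.0)
    t_plans, t_affines, t_truth = generate_cohort(test_spec)
    results = []
    # model mTs are sorted by descriptor, which matches the planted order
    # here (one mT per pattern), so planted bit-vectors identify strategies
    strategy_of = {}
    for s_idx, planted_bits in enumerate(t_truth.strategy_bits):
        strategy_of[s_idx] = next(
            st for st in bundle.strategies if st.bits == planted_bits)
    for plan in t_plans:
        strategy = strategy_of[t_truth.plan_strategy[plan.plan_id]]
        pairing = match_trajectories(
            init_plan(bundle, strategy.strategy_id, t_affines[plan.patient_id],
                      patient_id=plan.patient_id),
            plan, bundle)
        report = validate_mapping(pairing, bundle)
        results.extend(r.passed for r in report.pairs)
    observed = np.mean(results)

    # Monte-Carlo oracle: manual points are planted + N(0, sigma I3); the
    # mapped points sit at the estimated centroids; a pair passes when both
    # radial deviations are within twice the model's RMS dispersion.
    rng = np.random.default_rng(123)
    sigma = spec.noise_sigma_mm
    draws = 4000
    sig_ep = np.array([mt.sigma_entry for mt in bundle.mean_trajectories])
    sig_tp = np.array([mt.sigma_target for mt in bundle.mean_trajectories])
    passes = []
    for s_ep, s_tp in zip(sig_ep, sig_tp):
        d_ep = np.linalg.norm(rng.normal(0, sigma, (draws, 3)), axis=1)
        d_tp = np.linalg.norm(rng.normal(0, sigma, (draws, 3)), axis=1)
        passes.append(np.mean((d_ep <= 2 * s_ep) & (d_tp <= 2 * s_tp)))
    expected = np.mean(passes)
    assert observed == pytest.approx(expected, abs=0.05)


def test_end_to_end_identity_on_noiseless_cohort():
    """Noiseless cohort, identity jitter: initialising a training subject's
    own strategy reproduces the manual plan to < 1e-6 mm."""
    spec = CohortSpec(seed=5, n_strategies=2, mts_per_strategy=2, n_plans=8,
                      noise_sigma_mm=0.0, plan_dropout_prob=0.0,
                      affine_rot_deg=0.0, affine_scale=0.0, affine_trans_mm=0.0)
    volume, cfg = generate_atlas(spec)
    plans, affines, truth = generate_cohort(spec)
    bundle = build_model_bundle(plans, affines, volume, cfg, seed=spec.seed)
    from seegplan.pipeline import add_strategies
    add_strategies(bundle, cut_threshold=0.5)
    plan = plans[0]
    strategy = next(s for s in bundle.strategies if plan.plan_id in s.member_plan_ids)
    ip = init_plan(bundle, strategy.strategy_id, affines[plan.patient_id],
                   patient_id=plan.patient_id)
    pairing = match_trajectories(ip, plan, bundle)
    assert len(pairing.pairs) == plan.n_electrodes
    for _, _, ip_tr, mp_tr in pairing.pairs:
        assert ip_tr.entry.distance_to(mp_tr.entry) < 1e-6
        assert ip_tr.target.distance_to(mp_tr.target) < 1e-6
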