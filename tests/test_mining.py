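"""Candidate enumeration, evidence scoring, propagation, classification."""

import itertools

import numpy as np
import pytest

from cdpmine.chem import parse_formula
from cdpmine.fragments import Spectrum, cdp_fragments, make_cdp
from cdpmine.io import Annotation
from cdpmine.mining import (
    TIER_ORDER,
    PipelineConfig,
    build_delta_rules,
    classify_isomers,
    classify_unnatural,
    enumerate_candidates,
    propagate,
    revise_linear_to_cyclic,
    score_annotation,
)
from cdpmine.simulate import (
    FixtureSpec,
    PlantedCompound,
    generate_network,
    generate_spectrum,
    reference_cdp_annotations,
)


def noise_free_spectrum(pair, library, spectrum_id="s"):
    cand = make_cdp(*pair, library)
    peaks = np.array([(f.mz, 100.0) for f in cdp_fragments(cand)])
    return Spectrum(spectrum_id, cand.precursor_mz, peaks=peaks)


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mz,expected_member",
    [
        (257.1123, "cyclo(Hyp-MeEGlu)"),
        (155.0817, "cyclo(Gly-Pro)"),
    ],
)
def test_enumerate_includes_known_candidates(library, mz, expected_member):
    names = [c.name for c in enumerate_candidates(mz, 10.0, library)]
    assert expected_member in names


def test_enumerate_below_any_cdp_mass(library):
    assert enumerate_candidates(50.0, 10.0, library) == []


def test_enumerate_emits_both_leu_and_ile(library):
    names = {c.name for c in enumerate_candidates(211.1441, 10.0, library)}
    assert "cyclo(Pro-Leu)" in names and "cyclo(Pro-Ile)" in names


def test_enumeration_complete_over_reference_set(library):
    """Every reference CDP is recovered from its reported m/z at 20 ppm
    (rows flagged as m/z transcription errors fall back to the derived
    value; Leu/Ile ambiguity counts as present)."""
    from cdpmine.simulate import reference_cdp_table

    def collapse(name):
        return name.replace("Ile", "Leu")

    for row in reference_cdp_table(library).itertuples(index=False):
        query = row.theoretical_mz if row.mz_discrepant else row.observed_mz
        names = {collapse(c.name) for c in enumerate_candidates(query, 20.0, library)}
        assert collapse(row.name) in names, row.name


def test_enumerate_sorted_by_ppm_error(library):
    cands = enumerate_candidates(261.1237, 20.0, library)
    errs = [abs(c.precursor_mz - 261.1237) / c.precursor_mz for c in cands]
    assert errs == sorted(errs)


# --------------------------------------------------------------------------
# evidence scoring
# --------------------------------------------------------------------------

def test_score_noise_free_spectrum_confident(library, config):
    cand = make_cdp("MeEGlu", "Hyp", library)
    s = noise_free_spectrum(("MeEGlu", "Hyp"), library)
    score = score_annotation(s, cand, config)
    assert score.tier == "confident"
    assert set(score.residues_covered) == {"MeEGlu", "Hyp"}
    assert score.immonium_matches == 2


def test_score_empty_peaklist_weak(library, config):
    cand = make_cdp("Val", "Pro", library)
    s = Spectrum("e", cand.precursor_mz, peaks=np.empty((0, 2)))
    score = score_annotation(s, cand, config)
    assert score.tier == "weak"
    assert score.weighted_total == 0


def test_score_true_candidate_beats_composition_rival(library, config):
    # spectrum of cyclo(Val-Pro) scored against cyclo(Ala-Pro): brute
    # comparison of the two candidates on the same generated spectrum
    s = noise_free_spectrum(("Val", "Pro"), library)
    true_score = score_annotation(s, make_cdp("Val", "Pro", library), config)
    rival = score_annotation(s, make_cdp("Ala", "Pro", library), config)
    assert true_score.weighted_total > rival.weighted_total


def test_score_precursor_mismatch_flagged_weak(library, config):
    cand = make_cdp("Val", "Pro", library)
    s = noise_free_spectrum(("Val", "Pro"), library)
    s.precursor_mz += 1.0  # way outside 10 ppm
    score = score_annotation(s, cand, config)
    assert score.tier == "weak"
    assert not score.precursor_ok


def test_score_homodimer_single_immonium_covers_both(library, config):
    s = noise_free_spectrum(("Pro", "Pro"), library)
    score = score_annotation(s, make_cdp("Pro", "Pro", library), config)
    assert score.tier == "confident"


# --------------------------------------------------------------------------
# delta rules
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "delta_formula,mass,exchange",
    [
        ("C2H4", 28.0313, ("Ala", "Val")),
        ("C3H6", 42.0470, ("Ala", "Leu")),
        ("H2O", 18.0106, ("PyroGlu", "Glu")),
        ("O", 15.9949, ("Pro", "Hyp")),
        ("CH2", 14.0157, ("Glu", "MeEGlu")),
    ],
)
def test_delta_rules(library, delta_formula, mass, exchange):
    rules = build_delta_rules(library)
    rule = next(r for r in rules if r.composition_delta == parse_formula(delta_formula))
    assert rule.mass_delta == pytest.approx(mass, abs=1e-4)
    assert exchange in rule.exchanges
    assert rule.mass_delta == pytest.approx(rule.composition_delta.mass, abs=1e-4)


def test_delta_rules_exclude_leu_ile_and_dedupe(library):
    rules = build_delta_rules(library)
    for r in rules:
        assert r.mass_delta > 1e-9
        assert ("Leu", "Ile") not in r.exchanges
        assert ("Ile", "Leu") not in r.exchanges
    deltas = [r.composition_delta for r in rules]
    assert len(deltas) == len(set(deltas))


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------

def seed_for(bundle, name, library):
    net = bundle.network()
    fid = bundle.truth.loc[bundle.truth.name == name, "feature_id"].iloc[0]
    a, b = name[6:-1].split("-")
    return Annotation(
        node_id=fid,
        candidate=make_cdp(a, b, library),
        level="database",
        observed_mz=net.node_mz(fid),
        rt=net.node_rt(fid),
    )


def test_propagate_worked_example(pro_trio_bundle, library, config):
    """From seed cyclo(Val-Pro): Ala-Pro via -C2H4, Leu/Ile-Pro via +CH2."""
    net = pro_trio_bundle.network()
    seed = seed_for(pro_trio_bundle, "cyclo(Val-Pro)", library)
    anns = propagate(net, [seed], pro_trio_bundle.spectra_by_id(), config=config)
    by_name = {a.name: a for a in anns}
    assert "cyclo(Ala-Pro)" in by_name
    assert by_name["cyclo(Ala-Pro)"].level == "propagated"
    assert "cyclo(Leu/Ile-Pro)" in by_name
    assert by_name["cyclo(Leu/Ile-Pro)"].isomer_tag == "Leu/Ile"
    # seeds never overwritten
    assert by_name["cyclo(Pro-Val)"].level == "database"


def test_propagate_records_paths_and_soundness(pro_trio_bundle, library, config):
    net = pro_trio_bundle.network()
    seed = seed_for(pro_trio_bundle, "cyclo(Val-Pro)", library)
    anns = propagate(net, [seed], pro_trio_bundle.spectra_by_id(), config=config)
    for a in anns:
        if a.level == "propagated":
            assert a.path[0] == seed.node_id
            window = config.precursor_tol.window(a.theoretical_mz)
            assert abs(a.observed_mz - a.theoretical_mz) <= window


def test_propagate_fixpoint(pro_trio_bundle, library, config):
    net = pro_trio_bundle.network()
    seed = seed_for(pro_trio_bundle, "cyclo(Val-Pro)", library)
    spectra = pro_trio_bundle.spectra_by_id()
    once = propagate(net, [seed], spectra, config=config)
    twice = propagate(net, list(once), spectra, config=config)
    assert [(a.node_id, a.name, a.level) for a in once] == [
        (a.node_id, a.name, a.level) for a in twice
    ]


def test_propagate_isolated_node_stays_unannotated(library, config):
    spec = FixtureSpec(
        compounds=(
            PlantedCompound(("Val", "Pro"), 12.7),
            PlantedCompound(("Ala", "Pro"), 5.0),
            PlantedCompound(("Gly", "Gly"), 1.0),  # shares no diagnostics
        ),
        seed=3,
        ppm_sigma=2.0,
    )
    bundle = generate_network(spec)
    net = bundle.network()
    seed = seed_for(bundle, "cyclo(Val-Pro)", library)
    anns = propagate(net, [seed], bundle.spectra_by_id(), config=config)
    names = {a.name for a in anns}
    assert "cyclo(Gly-Gly)" not in names


def test_propagate_pyroglu_via_global_water_delta(library, config):
    """cyclo(Glu-Tyr) -> cyclo(PyroGlu-Tyr) across clusters via -H2O."""
    spec = FixtureSpec(
        compounds=(
            PlantedCompound(("Glu", "Tyr"), 10.26),
            PlantedCompound(("PyroGlu", "Tyr"), 11.45),
        ),
        seed=5,
        ppm_sigma=2.0,
        explicit_clusters={"cyclo(Glu-Tyr)": 2, "cyclo(PyroGlu-Tyr)": 4},
    )
    bundle = generate_network(spec)
    net = bundle.network()
    assert len(net.edges) == 0  # different clusters: no intra-cluster edge
    seed = seed_for(bundle, "cyclo(Glu-Tyr)", library)
    anns = propagate(net, [seed], bundle.spectra_by_id(), config=config)
    by_name = {a.name: a for a in anns}
    assert "cyclo(PyroGlu-Tyr)" in by_name
    assert by_name["cyclo(PyroGlu-Tyr)"].level == "propagated"


# --------------------------------------------------------------------------
# brute-force oracle for propagation on tiny networks
# --------------------------------------------------------------------------

def brute_force_best_assignment(net, seeds, spectra, config, library):
    """Exhaustive search over candidate assignments.

    Maximizes total weighted evidence subject to the same constraints
    propagation enforces: every assigned non-seed node must be reachable
    from a seed through assigned nodes via steps whose precursor delta
    matches a single residue exchange, and every assignment must reach
    the acceptance tier.
    """
    rules = build_delta_rules(library)
    seed_ids = {s.node_id: s for s in seeds}
    free = [n for n in net.nodes["feature_id"] if n not in seed_ids]
    options = {}
    for n in free:
        cands = []
        for c in enumerate_candidates(net.node_mz(n), config.precursor_ppm, library):
            if n not in spectra:
                continue
            score = score_annotation(spectra[n], c, config)
            if TIER_ORDER[score.tier] >= TIER_ORDER[config.accept_tier]:
                cands.append((c, score))
        options[n] = [None] + cands

    def delta_ok(u_cand, v_cand, d):
        for rule in rules:
            if abs(abs(d) - rule.mass_delta) > config.delta_tol_da:
                continue
            for f, t in rule.exchanges:
                heavy, light = (t, f)
                a, b = (u_cand, v_cand) if d > 0 else (v_cand, u_cand)
                # b is heavier than a by the rule delta
                ca, cb = list(a.residue_codes), list(b.residue_codes)
                if f in ca:
                    ca[ca.index(f)] = t
                    if sorted(ca) == sorted(cb):
                        return True
        return False

    g = net.graph()
    best = (-1.0, None)
    for combo in itertools.product(*(options[n] for n in free)):
        assign = {n: c for n, c in zip(free, combo) if c is not None}
        # support constraint: reachability from seeds via valid deltas
        supported = set(seed_ids)
        cand_of = {n: s.candidate for n, s in seed_ids.items()}
        cand_of.update({n: c for n, (c, _) in assign.items()})
        frontier = list(seed_ids)
        while frontier:
            u = frontier.pop()
            for v in g.neighbors(u):
                if v in supported or v not in assign:
                    continue
                if net.cluster_of(v) != net.cluster_of(u):
                    continue
                d = net.node_mz(v) - net.node_mz(u)
                if delta_ok(cand_of[u], cand_of[v], d):
                    supported.add(v)
                    frontier.append(v)
        if set(assign) - supported:
            continue
        total = sum(score.weighted_total for _, score in assign.values())
        if total > best[0]:
            best = (total, {n: c.formula.hill() for n, (c, _) in assign.items()})
    return best[1]


def test_propagate_matches_brute_force_oracle(library, config):
    specs = [
        FixtureSpec(
            compounds=(
                PlantedCompound(("Val", "Pro"), 12.7),
                PlantedCompound(("Ala", "Pro"), 5.0),
                PlantedCompound(("Leu", "Pro"), 18.8),
            ),
            seed=21,
            ppm_sigma=2.0,
        ),
        FixtureSpec(
            compounds=(
                PlantedCompound(("Gly", "Pro"), 3.6),
                PlantedCompound(("Ala", "Pro"), 5.0),
                PlantedCompound(("Val", "Pro"), 12.7),
                PlantedCompound(("Ser", "Pro"), 1.2),
            ),
            seed=22,
            ppm_sigma=2.0,
        ),
    ]
    for spec in specs:
        bundle = generate_network(spec)
        net = bundle.network()
        name = bundle.truth.iloc[0]["name"]
        seed_name = "cyclo(Val-Pro)"
        seed = seed_for(bundle, seed_name, library)
        spectra = bundle.spectra_by_id()
        anns = propagate(net, [seed], spectra, config=config)
        ours = {
            a.node_id: a.formula.hill() for a in anns if a.node_id != seed.node_id
        }
        oracle = brute_force_best_assignment(net, [seed], spectra, config, library)
        assert ours == oracle


# --------------------------------------------------------------------------
# de novo revision
# --------------------------------------------------------------------------

def _revision_bundle():
    return generate_network(
        FixtureSpec(
            compounds=(
                PlantedCompound(("Val", "Pro"), 12.71),
                PlantedCompound(("Tyr", "Pro"), 13.31, denovo=True,
                                dehydrated_tag=True),
            ),
            seed=9,
            ppm_sigma=2.0,
        )
    )


def test_revise_dehydrated_dipeptide_to_cdp(library, config):
    from cdpmine.io import DeNovoHit

    bundle = _revision_bundle()
    net = bundle.network()
    spectra = bundle.spectra_by_id()
    existing = [seed_for(bundle, "cyclo(Val-Pro)", library)]
    tyr_node = bundle.truth.loc[
        bundle.truth.name == "cyclo(Tyr-Pro)", "feature_id"
    ].iloc[0]
    hit = DeNovoHit(sequence=("Tyr", "Pro"), alc=72.0, feature_id=tyr_node,
                    modifications=((1, -18.01),))
    (ann,) = revise_linear_to_cyclic([hit], net, spectra, config, existing, library)
    assert ann.level == "revised"
    assert ann.name == "cyclo(Pro-Tyr)"
    assert any(h.startswith("denovo:") for h in ann.history)


def test_revise_requires_cdp_in_cluster(library, config):
    from cdpmine.io import DeNovoHit

    bundle = _revision_bundle()
    net = bundle.network()
    spectra = bundle.spectra_by_id()
    tyr_node = bundle.truth.loc[
        bundle.truth.name == "cyclo(Tyr-Pro)", "feature_id"
    ].iloc[0]
    hit = DeNovoHit(sequence=("Tyr", "Pro"), alc=72.0, feature_id=tyr_node,
                    modifications=((1, -18.01),))
    # no existing CDP annotations anywhere: revision is withheld
    (ann,) = revise_linear_to_cyclic([hit], net, spectra, config, [], library)
    assert ann.level == "denovo"


def test_revise_passes_through_longer_peptides(library, config):
    from cdpmine.io import DeNovoHit

    bundle = generate_network(
        FixtureSpec(
            compounds=(
                PlantedCompound(("Leu", "Pro", "Pro", "Leu"), 20.0, kind="linear"),
            ),
            seed=13,
        )
    )
    net = bundle.network()
    hit = DeNovoHit(sequence=("Leu", "Pro", "Pro", "Leu"), alc=90.0,
                    feature_id=bundle.truth.iloc[0]["feature_id"])
    (ann,) = revise_linear_to_cyclic(
        [hit], net, bundle.spectra_by_id(), config, [], library
    )
    assert ann.level == "denovo"
    assert ann.name == "Leu-Pro-Pro-Leu"


# --------------------------------------------------------------------------
# isomer / unnatural classification
# --------------------------------------------------------------------------

def test_reference_set_isomer_pairs(library):
    anns = reference_cdp_annotations(library)
    groups = classify_isomers(anns)
    pairs = [g for g in groups if g.relation == "diastereomer_pair"]
    assert len(pairs) == 16


def test_reference_set_unnatural_count(library):
    counts = classify_unnatural(reference_cdp_annotations(library))
    assert counts == {"total": 53, "unnatural": 15, "natural": 38}


def test_positional_isomers_same_formula_different_composition(library):
    anns = [
        Annotation("n1", make_cdp("Tyr", "Hyp", library), "deep_mined",
                   277.1171, rt=12.43),
        Annotation("n2", make_cdp("Glu", "Phe", library), "deep_mined",
                   277.1178, rt=20.30),
    ]
    groups = classify_isomers(anns)
    assert [g.relation for g in groups] == ["positional_isomers"]


def test_leu_ile_rt_heuristic_assigns_ile_earlier(library):
    anns = [
        Annotation("n1", make_cdp("Ala", "Leu", library), "deep_mined",
                   185.1281, rt=13.34),
        Annotation("n2", make_cdp("Ala", "Leu", library), "deep_mined",
                   185.1283, rt=12.02),
    ]
    classify_isomers(anns, leu_ile_rt=True)
    by_rt = sorted(anns, key=lambda a: a.rt)
    assert "Ile" in by_rt[0].name
    assert "Leu" in by_rt[1].name


def test_all_unique_formulas_no_pairs(library):
    anns = [
        Annotation("n1", make_cdp("Gly", "Pro", library), "deep_mined", 155.08, rt=3.6),
        Annotation("n2", make_cdp("Val", "Pro", library), "deep_mined", 197.13, rt=12.7),
    ]
    assert classify_isomers(anns) == []


def test_classify_isomers_permutation_invariant(library):
    anns = reference_cdp_annotations(library)
    base = classify_isomers(anns)
    rng = np.random.default_rng(4)
    shuffled = [anns[i] for i in rng.permutation(len(anns))]
    other = classify_isomers(shuffled)
    key = lambda gs: sorted(
        (g.formula.hill(), g.relation, tuple(sorted(a.node_id for a in g.members)))
        for g in gs
    )
    assert key(base) == key(other)


def test_unnatural_flag_per_candidate(library):
    assert not make_cdp("Gly", "Pro", library).unnatural
    assert make_cdp("MeEGlu", "Hyp", library).unnatural
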