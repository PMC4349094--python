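import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emcsim.alleles import Edit, MismatchMap, MismatchSite, VariantSpec, apply_variants, map_mismatches
from emcsim.digestion import (
    CleavageSite,
    EnzymeProfile,
    bulge_class,
    cleavage_sites,
    duplex_product_sizes,
    full_digest,
    heteroduplex_digests,
    partial_digest,
    population_fragments,
)
from emcsim.reanneal import MixSpec, reanneal


def _sites(positions, p=0.5):
    return [CleavageSite(pos, p, "SNV") for pos in positions]


# ---------------------------------------------------------------- full digest


@pytest.mark.parametrize(
    "allele,expected_wt",
    [
        ("d15", {4, 39, 46, 195, 204}),
        ("d19", {32, 46, 49, 141, 220}),
    ],
)
def test_complex_allele_full_digest_fragment_sets(allele, expected_wt, exon2a, t7e1, request):
    """Whole digests of the two sequenced alleles give the documented fragments."""
    v = request.getfixturevalue(allele)
    mut = apply_variants(exon2a, v)
    sites = cleavage_sites(map_mismatches(exon2a, v), t7e1)
    wt_fr, mut_fr = full_digest(sites, exon2a.length, mut.length)
    assert set(wt_fr) == expected_wt
    assert sum(wt_fr) == exon2a.length
    assert sum(mut_fr) == mut.length == 487


def test_no_sites_leaves_amplicon_intact():
    wt_fr, mut_fr = full_digest([], 488, 488)
    assert wt_fr == (488,) and mut_fr == (488,)


def test_duplicate_positions_rejected():
    with pytest.raises(ValueError):
        full_digest(_sites([46, 46]), 488, 488)


def test_site_positions_must_be_internal():
    with pytest.raises(ValueError):
        full_digest(_sites([488]), 488, 488)


# -------------------------------------------------------------- partial digest


def test_partial_digest_enumerates_all_cut_subsets(exon2a, d15, t7e1):
    mut = apply_variants(exon2a, d15)
    sites = cleavage_sites(map_mismatches(exon2a, d15), t7e1)
    res = partial_digest(sites, exon2a.length, mut.length)
    assert len(res.states) == 16
    assert sum(s.probability for s in res.states) == pytest.approx(1.0, abs=1e-9)


def test_single_certain_cut_yields_two_fragments():
    res = partial_digest([CleavageSite(100, 1.0, "SNV")], 488, 488)
    certain = [s for s in res.states if s.probability > 0]
    assert len(certain) == 1
    assert [f.apparent_size for f in certain[0].fragments] == [100, 388]


def test_single_cut_at_shared_deletion_site(exon2a, d15, t7e1):
    """Cutting only the position-46 lesion leaves ~440-bp companions."""
    mut = apply_variants(exon2a, d15)
    sites = cleavage_sites(map_mismatches(exon2a, d15), t7e1)
    res = partial_digest(sites, exon2a.length, mut.length)
    (state,) = [s for s in res.states if s.cut_sites == (0,)]
    assert [f.wt_strand for f in state.fragments] == [46, 442]


def test_length_conservation_in_every_state(exon2a, d15, t7e1):
    mut = apply_variants(exon2a, d15)
    for orientation, res in heteroduplex_digests(
        map_mismatches(exon2a, d15), t7e1, exon2a.length, mut.length
    ).items():
        for state in res.states:
            assert sum(f.wt_strand for f in state.fragments) == exon2a.length
            assert sum(f.mut_strand for f in state.fragments) == mut.length


def test_all_certain_cuts_collapse_to_full_digest(exon2a, d19, t7e1):
    mut = apply_variants(exon2a, d19)
    sites = [
        CleavageSite(s.position, 1.0, s.lesion_kind, s.bulge_size, s.bulge_strand)
        for s in cleavage_sites(map_mismatches(exon2a, d19), t7e1)
    ]
    res = partial_digest(sites, exon2a.length, mut.length)
    certain = [s for s in res.states if s.probability > 0]
    assert len(certain) == 1 and certain[0].probability == pytest.approx(1.0)
    wt_fr, mut_fr = full_digest(sites, exon2a.length, mut.length)
    assert tuple(f.wt_strand for f in certain[0].fragments) == wt_fr
    assert tuple(f.mut_strand for f in certain[0].fragments) == mut_fr


def test_too_many_sites_rejected():
    sites = _sites(range(10, 10 + 17 * 5, 5))
    with pytest.raises(ValueError, match="cap"):
        partial_digest(sites, 488, 488)


def test_raising_p_cut_never_reduces_full_digest_abundance():
    base = [CleavageSite(100, 0.3, "SNV"), CleavageSite(250, 0.6, "SNV")]
    full_state_prob = lambda res: res.states[-1].probability  # all-cut subset

    prev = 0.0
    for p in (0.3, 0.5, 0.8, 1.0):
        sites = [CleavageSite(100, p, "SNV"), base[1]]
        res = partial_digest(sites, 488, 488)
        prob = next(s.probability for s in res.states if len(s.cut_sites) == 2)
        assert prob >= prev
        prev = prob


@given(
    st.lists(st.integers(20, 460), unique=True, min_size=1, max_size=6),
    st.lists(st.floats(0.05, 0.95), min_size=6, max_size=6),
    st.integers(0, 2**31 - 1),
)
def test_partial_digest_matches_monte_carlo_oracle(positions, probs, seed):
    """Analytic subset weights agree with independent Bernoulli sampling."""
    positions = sorted(positions)
    sites = [
        CleavageSite(pos, p, "SNV") for pos, p in zip(positions, probs)
    ]
    res = partial_digest(sites, 488, 488)
    analytic = res.fragment_abundances()

    k = len(sites)
    n_draws = 100_000
    rng = np.random.default_rng(seed)
    draws = rng.random((n_draws, k)) < np.array([s.p_cut for s in sites])
    weights = 2 ** np.arange(k)
    codes = draws @ weights
    counts = np.bincount(codes, minlength=2**k)

    # count of each fragment per subset, to form the empirical estimate
    # and its multinomial standard error
    frag_index = {f: i for i, f in enumerate(analytic)}
    c = np.zeros((2**k, len(frag_index)))
    p_state = np.zeros(2**k)
    for state in res.states:
        code = sum(2**i for i in state.cut_sites)
        p_state[code] = state.probability
        for f in state.fragments:
            c[code, frag_index[f]] += 1
    empirical = counts @ c / n_draws
    mean = p_state @ c
    se = np.sqrt(np.maximum(p_state @ c**2 - mean**2, 0.0) / n_draws)
    # 4.5 se keeps the family-wise false-alarm rate negligible across the
    # hundreds of fragment comparisons this property generates
    for f, i in frag_index.items():
        assert abs(empirical[i] - analytic[f]) <= 4.5 * se[i] + 1e-12


# ------------------------------------------------------ strand-resolved sizes


def test_deletion_doublet_differs_by_bulge_size(exon3, del20_exon3, t7e1):
    mut = apply_variants(exon3, del20_exon3)
    digs = heteroduplex_digests(
        map_mismatches(exon3, del20_exon3), t7e1, exon3.length, mut.length
    )
    sizes = duplex_product_sizes(digs)
    products = sorted(s for s in sizes if s != max(sizes))
    small_pair, large_pair = products[:2], products[2:]
    assert small_pair[1] - small_pair[0] == 20
    assert large_pair[1] - large_pair[0] == 20


def test_snv_heteroduplex_has_no_doublet(exon2a, t7e1):
    v = VariantSpec([Edit(150, "substitution", ref=exon2a.sequence[149],
                          alt="G" if exon2a.sequence[149] != "G" else "A")])
    digs = heteroduplex_digests(map_mismatches(exon2a, v), t7e1, 488, 488)
    a = digs["wt_sense"].sized_abundances()
    b = digs["mut_sense"].sized_abundances()
    assert a == b  # both orientations give identical product sizes


def test_single_nt_deletion_doublet_is_one_bp(exon2a, t7e1):
    v = VariantSpec([Edit(46, "deletion", ref=exon2a.sequence[45])])
    mut = apply_variants(exon2a, v)
    digs = heteroduplex_digests(map_mismatches(exon2a, v), t7e1, 488, 487)
    cut_sizes = {
        o: sorted(
            f.apparent_size
            for s in d.states
            if s.cut_sites
            for f in s.fragments
        )
        for o, d in digs.items()
    }
    small = sorted(min(v) for v in cut_sizes.values())
    assert small[1] - small[0] == 1  # collapses under sizing tolerance downstream


# ------------------------------------------------------------- enzyme profiles


def test_bulge_classes():
    assert bulge_class(1) == "1"
    assert bulge_class(12) == "2-19"
    assert bulge_class(20) == "20+"
    with pytest.raises(ValueError):
        bulge_class(0)


def test_t7e1_prefers_bulges_over_snvs(exon2a, d15, t7e1):
    sites = cleavage_sites(map_mismatches(exon2a, d15), t7e1)
    assert len(sites) == 4
    bulge = next(s for s in sites if s.lesion_kind == "bulge")
    snvs = [s for s in sites if s.lesion_kind == "SNV"]
    assert all(bulge.p_cut > s.p_cut for s in snvs)


def test_surveyor_cleaves_twenty_nt_bulge(exon3, del20_exon3, surveyor):
    (site,) = cleavage_sites(map_mismatches(exon3, del20_exon3), surveyor)
    assert site.p_cut == surveyor.p_cut_bulge["20+"] > 0


def test_surveyor_prefers_snvs_relative_to_t7e1(t7e1, surveyor):
    assert surveyor.p_cut_snv > t7e1.p_cut_snv


def test_profile_validation():
    with pytest.raises(ValueError):
        EnzymeProfile("bad", 1.5, {"1": 0.5, "2-19": 0.5, "20+": 0.5})
    with pytest.raises(ValueError):
        EnzymeProfile("bad", 0.5, {"1": 0.5})


# --------------------------------------------------------------- populations


def test_population_fragments_conserve_molar_abundance(exon3, del20_exon3, t7e1):
    mut = apply_variants(exon3, del20_exon3)
    pop = reanneal(MixSpec(0.3))
    frags = population_fragments(
        pop, map_mismatches(exon3, del20_exon3), t7e1, exon3.length, mut.length
    )
    # every cut splits one duplex into two: total molar count is
    # 1 + f_hetero * p_cut per mole of input duplexes
    expected = 1.0 + pop.f_hetero * t7e1.p_cut_bulge["20+"]
    assert sum(frags.values()) == pytest.approx(expected, abs=1e-12)
    # mass conservation in apparent-size terms for this single-cut digest
    total_mass = sum(s * a for s, a in frags.items())
    assert total_mass == pytest.approx(
        572 * (pop.f_wt_homo + pop.f_hetero) + 552 * pop.f_mut_homo, abs=1e-9
    )
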