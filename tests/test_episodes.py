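"""Episode construction: chaining, boundaries, censoring, costs, oracle."""

from datetime import timedelta

import pytest

from pcekit import (
    ScenarioConfig,
    Sector,
    StudyConfig,
    ValidationError,
    attach_community_care,
    build_all_episodes,
    build_episodes,
    episode_cost,
    generate_encounters,
    generate_population,
)
from pcekit.episodes import allocated_amount_cents
from pcekit.records_io import INSTITUTIONAL_SECTORS

from conftest import START, brute_force_partition, day, make_enc, make_person


def built_partition(episodes):
    return {frozenset(ep.member_institutional_ids) for ep in episodes}


class TestChaining:
    def test_single_acute_stay_gets_30_day_tail(self, config):
        encs = [make_enc("a", admit=0, discharge=5)]
        episodes, unalloc = build_episodes(encs, make_person(), config)
        assert len(episodes) == 1 and unalloc == []
        ep = episodes[0]
        assert ep.start_date == day(0)
        assert ep.final_discharge_date == day(5)
        assert ep.end_date == day(35)

    @pytest.mark.parametrize(
        "rehab_admit, chained",
        [(35, True), (36, False)],  # gap 30 chains, gap 31 splits
    )
    def test_window_boundary(self, config, rehab_admit, chained):
        encs = [
            make_enc("a", admit=0, discharge=5),
            make_enc("r", sector=Sector.inpatient_rehab, admit=rehab_admit,
                     discharge=rehab_admit + 10),
        ]
        episodes, unalloc = build_episodes(encs, make_person(), config)
        if chained:
            assert len(episodes) == 1
            assert episodes[0].member_institutional_ids == ["a", "r"]
        else:
            # rehab alone cannot anchor: it is unallocated, episode ends d35
            assert len(episodes) == 1
            assert episodes[0].member_institutional_ids == ["a"]
            assert episodes[0].end_date == day(35)
            assert unalloc == ["r"]

    def test_ltc_without_prior_acute_contact_is_unallocated(self, config):
        encs = [make_enc("l", sector=Sector.long_term_care, admit=10, discharge=60)]
        episodes, unalloc = build_episodes(encs, make_person(), config)
        assert episodes == [] and unalloc == ["l"]

    def test_nonacute_never_joins(self, config):
        encs = [
            make_enc("a", admit=0, discharge=5),
            make_enc("n", sector=Sector.inpatient_nonacute, admit=10, discharge=12),
        ]
        episodes, unalloc = build_episodes(encs, make_person(), config)
        assert episodes[0].member_institutional_ids == ["a"]
        assert unalloc == ["n"]

    def test_same_day_transfer_chains(self, config):
        encs = [
            make_enc("a", admit=0, discharge=5),
            make_enc("b", sector=Sector.inpatient_rehab, admit=5, discharge=20),
        ]
        episodes, _ = build_episodes(encs, make_person(), config)
        assert episodes[0].member_institutional_ids == ["a", "b"]

    def test_overlapping_stays_chain_with_max_window(self, config):
        # long CCC stay keeps the window open past the short acute readmission
        encs = [
            make_enc("a", admit=0, discharge=2),
            make_enc("c", sector=Sector.complex_continuing_care, admit=10, discharge=80),
            make_enc("b", admit=60, discharge=62),
        ]
        episodes, _ = build_episodes(encs, make_person(), config)
        assert episodes[0].member_institutional_ids == ["a", "c", "b"]
        assert episodes[0].final_discharge_date == day(80)

    def test_ed_anchor_configurable(self):
        encs = [make_enc("e", sector=Sector.emergency, admit=10, discharge=10)]
        on = StudyConfig(ed_starts_episode=True)
        off = StudyConfig(ed_starts_episode=False)
        eps_on, un_on = build_episodes(encs, make_person(), on)
        eps_off, un_off = build_episodes(encs, make_person(), off)
        assert len(eps_on) == 1 and un_on == []
        assert eps_off == [] and un_off == ["e"]

    def test_duplicate_encounter_ids_rejected(self, config):
        encs = [make_enc("a", admit=0, discharge=5), make_enc("a", admit=10, discharge=11)]
        with pytest.raises(ValidationError, match="duplicate"):
            build_episodes(encs, make_person(), config)


class TestCensoring:
    def test_open_discharge_treated_as_study_end(self, config):
        encs = [make_enc("a", admit=300, discharge="open")]
        episodes, _ = build_episodes(encs, make_person(), config)
        assert episodes[0].final_discharge_date == config.study_end
        assert episodes[0].end_date == config.study_end

    def test_window_open_at_study_end_is_censored_not_dropped(self, config):
        encs = [make_enc("a", admit=350, discharge=360)]
        episodes, _ = build_episodes(encs, make_person(), config)
        assert len(episodes) == 1
        assert episodes[0].end_date == config.study_end

    def test_death_inside_stay_ends_episode_at_death(self, config):
        person = make_person(death_date=day(10))
        encs = [make_enc("a", admit=0, discharge=50)]
        episodes, _ = build_episodes(encs, person, config)
        assert episodes[0].final_discharge_date == day(10)
        assert episodes[0].end_date == day(10)

    def test_no_end_date_exceeds_study_end_or_death(self, small_synthetic, config):
        persons, encounters, _ = small_synthetic
        episodes, _ = build_all_episodes(encounters, persons, config)
        death = {p.person_id: p.death_date for p in persons}
        for ep in episodes:
            assert ep.end_date <= config.study_end
            if death[ep.person_id]:
                assert ep.end_date <= death[ep.person_id]


class TestCommunityAttachment:
    def _episode(self, config):
        encs = [make_enc("a", admit=0, discharge=5)]
        episodes, _ = build_episodes(encs, make_person(), config)
        return episodes

    @pytest.mark.parametrize("visit_day, attached", [(35, True), (36, False)])
    def test_tail_boundary(self, config, visit_day, attached):
        episodes = self._episode(config)
        visit = make_enc("v", sector=Sector.physician, admit=visit_day)
        unattached = attach_community_care(episodes, [visit], config)
        assert (episodes[0].community_ids == ["v"]) is attached
        assert (unattached == []) is attached

    def test_visit_in_intermediate_gap_is_attached(self, config):
        encs = [
            make_enc("a", admit=0, discharge=5),
            make_enc("b", admit=20, discharge=25),
        ]
        episodes, _ = build_episodes(encs, make_person(), config)
        visit = make_enc("v", sector=Sector.drug, admit=12)
        attach_community_care(episodes, [visit], config)
        assert episodes[0].community_ids == ["v"]

    def test_visit_before_start_unallocated(self, config):
        episodes = self._episode(config)
        visit = make_enc("v", sector=Sector.home_care, admit=364)
        assert attach_community_care(episodes, [visit], config) == ["v"]


class TestEpisodeCost:
    def test_sums_members_and_community(self, config):
        encs = [
            make_enc("a", admit=0, discharge=5, cost=100.0),
            make_enc("b", sector=Sector.inpatient_rehab, admit=10, discharge=20, cost=200.0),
            make_enc("v", sector=Sector.physician, admit=30, cost=50.0),
        ]
        episodes, _ = build_episodes(encs, make_person(), config)
        attach_community_care(episodes, encs, config)
        total, per_sector = episode_cost(episodes[0], {e.encounter_id: e for e in encs}, config)
        assert total == 35000
        assert per_sector[Sector.physician] == 5000

    def test_per_diem_stay_prorated_past_episode_end(self, config):
        # 100-day long-term-care stay, death censors the episode at day 44:
        # 40 of 100 stay days fall inside -> 40% of the cost attributed
        person = make_person(death_date=day(44))
        encs = [
            make_enc("a", admit=0, discharge=1, cost=0.0),
            make_enc("l", sector=Sector.long_term_care, admit=5, discharge=104, cost=10_000.0),
        ]
        episodes, _ = build_episodes(encs, person, config)
        (ep,) = episodes
        assert ep.end_date == day(44)
        assert allocated_amount_cents(encs[1], ep, config) == 400_000  # $4,000

    def test_total_cost_conserved_on_synthetic_run(self, small_synthetic, config):
        persons, encounters, _ = small_synthetic
        episodes, membership = build_all_episodes(encounters, persons, config)
        allocated = sum(ep.total_cost_cents for ep in episodes)
        episodes_by_key = {ep.episode_key: ep for ep in episodes}
        remaining = 0
        for enc in encounters:
            key = membership[enc.encounter_id]
            if key == "unallocated":
                remaining += enc.cost_cents
            else:
                remaining += enc.cost_cents - allocated_amount_cents(
                    enc, episodes_by_key[key], config
                )
        assert allocated + remaining == sum(e.cost_cents for e in encounters)


class TestPartitionProperties:
    def test_partition_is_exact_and_exclusive(self, small_synthetic, config):
        persons, encounters, _ = small_synthetic
        episodes, membership = build_all_episodes(encounters, persons, config)
        inst = [e for e in encounters if e.sector in INSTITUTIONAL_SECTORS]
        seen = set()
        for ep in episodes:
            for eid in ep.member_institutional_ids:
                assert eid not in seen
                seen.add(eid)
        for enc in inst:
            assert enc.encounter_id in membership

    def test_recovers_planted_partition(self, small_synthetic, config):
        persons, encounters, gt = small_synthetic
        episodes, membership = build_all_episodes(encounters, persons, config)
        assert built_partition(episodes) == gt.partition()
        inst = {e.encounter_id for e in encounters if e.sector in INSTITUTIONAL_SECTORS}
        assert {i for i in inst if membership[i] == "unallocated"} == gt.unallocated()

    def test_agrees_with_brute_force_oracle(self, codemap, config):
        sc = ScenarioConfig(n_persons=100, seed=21)
        persons = generate_population(sc)
        encounters, _ = generate_encounters(persons, sc, codemap, config)
        by_person = {}
        for e in encounters:
            by_person.setdefault(e.person_id, []).append(e)
        for p in persons:
            encs = by_person.get(p.person_id, [])
            episodes, unalloc = build_episodes(encs, p, config)
            oracle_part, oracle_un = brute_force_partition(encs, p, config)
            assert built_partition(episodes) == oracle_part
            assert set(unalloc) == oracle_un

    def test_separation_between_consecutive_episodes(self, small_synthetic, config):
        persons, encounters, _ = small_synthetic
        episodes, _ = build_all_episodes(encounters, persons, config)
        enc_admit = {e.encounter_id: e.admit_date for e in encounters}
        by_person = {}
        for ep in episodes:
            by_person.setdefault(ep.person_id, []).append(ep)
        for eps in by_person.values():
            eps.sort(key=lambda e: e.start_date)
            for e1, e2 in zip(eps, eps[1:]):
                anchor_admit = enc_admit[e2.anchor_encounter_id]
                assert (anchor_admit - e1.final_discharge_date).days > config.window_days
                assert e1.end_date < e2.start_date

    def test_widening_window_never_creates_episodes(self, codemap):
        sc = ScenarioConfig(n_persons=60, seed=13)
        persons = generate_population(sc)
        narrow = StudyConfig(window_days=30)
        wide = StudyConfig(window_days=60)
        encounters, _ = generate_encounters(persons, sc, codemap, narrow)
        by_person = {}
        for e in encounters:
            by_person.setdefault(e.person_id, []).append(e)
        for p in persons:
            encs = by_person.get(p.person_id, [])
            n_narrow = len(build_episodes(encs, p, narrow)[0])
            n_wide = len(build_episodes(encs, p, wide)[0])
            assert n_wide <= n_narrow
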