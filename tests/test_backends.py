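"""Backend registry, the deterministic matcher, parsing and error injection."""
import json
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synoptex import (ABSTAIN, BackendError, ExtractionRecord, inject_errors,
                      normalize, oracle_match, parse_response, segment_report,
                      select_backend, serialize_record)
from synoptex.prompts import build_prompt


class TestRegistry:
    def test_oracle_is_deterministic(self, schema):
        be = select_backend("oracle", {"schema": schema})
        seg = segment_report("Tumor focality: Multiple foci", schema)[0]
        bundle = build_prompt(seg, schema.field("focality"))
        assert be.complete(bundle, seg.text) == be.complete(bundle, seg.text)

    def test_noisy_oracle_reproducible_for_fixed_seed(self, schema):
        seg = segment_report("Tumor focality: Multiple foci", schema)[0]
        bundle = build_prompt(seg, schema.field("focality"))
        outs = []
        for _ in range(2):
            be = select_backend(
                "oracle-noisy",
                {"schema": schema, "seed": 5, "rates": (0.5, 0.3, 0.0)})
            outs.append([be.complete(bundle, seg.text) for _ in range(20)])
        assert outs[0] == outs[1]

    def test_unknown_backend_lists_available(self):
        with pytest.raises(BackendError, match="oracle"):
            select_backend("gpt-99")


class TestOracleMatch:
    def test_numeric_template_with_found_number(self, schema):
        spec = schema.field("dcis_margin_exact")
        value, extra = oracle_match(
            spec, "Distance from DCIS to Anterior Margin: Exact distance: mm. "
                  "Found number 4")
        assert value == "Exact distance: — mm"
        assert extra == 4

    def test_abstains_on_distractor_text(self, schema):
        spec = schema.field("distant_sites")
        value, extra = oracle_match(
            spec, "Distant Site(s) Involved: Comment(s):. nan. Some other "
                  "free text.")
        assert value is None and extra is None

    def test_synonym_maps_to_canonical_option(self, schema):
        spec = schema.field("histologic_type")
        value, _ = oracle_match(spec, "Histologic type: IDC")
        assert value == "Invasive ductal carcinoma"

    def test_longer_option_beats_its_substring(self, schema):
        spec = schema.field("dcis_present")
        value, _ = oracle_match(
            spec, "Ductal carcinoma in situ: Present, extensive intraductal "
                  "component")
        assert value == "Present, extensive intraductal component"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, schema, seed):
        """Exhaustive oracle: longest option whose normalized form occurs."""
        rng = random.Random(seed)
        specs = [s for s in schema.fields.values()
                 if s.value_kind == "categorical"]
        for spec in rng.sample(specs, 20):
            embedded = rng.sample(list(spec.allowed_options),
                                  rng.randint(0, min(2, len(spec.allowed_options))))
            text = f"{spec.subsection}: " + " and ".join(embedded) + ". nan"
            value, _ = oracle_match(spec, text)
            hay = normalize(text)
            occurring = [o for o in spec.allowed_options
                         if normalize(o) in hay]
            for canon, alts in spec.synonyms.items():
                if any(normalize(a) in hay for a in alts):
                    occurring.append(canon)
            if not occurring:
                assert value is None
            else:
                best_len = max(len(normalize(o)) for o in occurring)
                best = [o for o in occurring
                        if len(normalize(o)) == best_len]
                assert value in best


class TestParseResponse:
    def test_strict_json_is_ok(self, schema):
        raw = '{"field":"adh","value":"Atypical ductal hyperplasia"}'
        rec = parse_response(raw, schema.field("adh"))
        assert rec.status == "ok"
        assert rec.value == "Atypical ductal hyperplasia"

    def test_prose_wrapped_json_is_repaired(self, schema):
        raw = ('Sure! Here is the JSON: '
               '{"field":"adh","value":"Atypical ductal hyperplasia"}')
        rec = parse_response(raw, schema.field("adh"))
        assert rec.status == "repaired"
        assert rec.value == "Atypical ductal hyperplasia"

    def test_fenced_json_is_repaired(self, schema):
        raw = '```json\n{"field":"adh","value":null}\n```'
        rec = parse_response(raw, schema.field("adh"))
        assert rec.status == "repaired"
        assert rec.value == ABSTAIN

    def test_truncated_json_is_invalid(self, schema):
        rec = parse_response('{"value": 42', schema.field("adh"))
        assert rec.status == "invalid"
        assert rec.raw_response == '{"value": 42'

    def test_off_ontology_value_is_invalid_with_raw_retained(self, schema):
        raw = '{"field":"adh","value":"8 o\'clock"}'
        rec = parse_response(raw, schema.field("adh"))
        assert rec.status == "invalid"
        assert rec.value == ABSTAIN
        assert rec.raw_response == raw

    def test_value_normalization_tolerates_case_space_and_dash(self, schema):
        raw = json.dumps({"field": "distant_sites",
                          "value": "non–regional  LYMPH node(s)"})
        rec = parse_response(raw, schema.field("distant_sites"))
        assert rec.status == "ok"
        assert rec.value == "Non-regional lymph node(s)"

    @given(st.sampled_from(["adh", "dcis_margin_exact", "procedure"]),
           st.integers(0, 10), st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_parse_of_serialize_is_identity(self, schema, fid, extra_seed,
                                            abstain):
        spec = schema.field(fid)
        if abstain or not spec.allowed_options:
            value, extra = ABSTAIN, None
        else:
            value = spec.allowed_options[extra_seed % len(spec.allowed_options)]
            extra = extra_seed if spec.value_kind == "numeric_template" else None
        rec = ExtractionRecord(report_id="r", field_id=fid, value=value,
                               extra=extra, backend_id="oracle")
        parsed = parse_response(serialize_record(rec), spec, report_id="r",
                                backend_id="oracle")
        assert parsed.status == "ok"
        assert (parsed.value, parsed.extra) == (rec.value, rec.extra)


class TestInjectErrors:
    def _record(self, schema, value, extra=None):
        return ExtractionRecord(report_id="r", field_id="procedure",
                                value=value, extra=extra)

    def test_zero_rates_are_identity(self, schema):
        rec = self._record(schema, "Total mastectomy")
        assert inject_errors(rec, schema.field("procedure"),
                             (0.0, 0.0, 0.0), 1) is rec

    def test_full_drop_forces_abstention(self, schema):
        rec = self._record(schema, "Total mastectomy")
        out = inject_errors(rec, schema.field("procedure"), (0.0, 1.0, 0.0), 1)
        assert out.value == ABSTAIN

    def test_full_swap_picks_a_different_option(self, schema):
        rec = self._record(schema, "Total mastectomy")
        out = inject_errors(rec, schema.field("procedure"), (1.0, 0.0, 0.0), 3)
        assert out.value != "Total mastectomy"
        assert out.value in schema.field("procedure").allowed_options

    def test_spurious_on_abstention(self, schema):
        rec = self._record(schema, ABSTAIN)
        out = inject_errors(rec, schema.field("procedure"), (0.0, 0.0, 1.0), 2)
        assert out.value in schema.field("procedure").allowed_options

    @pytest.mark.parametrize("rates", [(-0.1, 0, 0), (0, 1.2, 0), (0.6, 0.6, 0)])
    def test_invalid_rates_rejected(self, schema, rates):
        rec = self._record(schema, "Total mastectomy")
        with pytest.raises(ValueError):
            inject_errors(rec, schema.field("procedure"), rates, 0)

    def test_drop_rate_recovered_within_three_binomial_se(self, schema):
        """Binomial sampling oracle: eps_drop=0.1 over 445 positive records."""
        spec = schema.field("procedure")
        n, eps = 445, 0.1
        kept = 0
        for i in range(n):
            rec = self._record(schema, "Total mastectomy")
            out = inject_errors(rec, spec, (0.0, eps, 0.0), 1000 + i)
            kept += out.value != ABSTAIN
        se = math.sqrt(eps * (1 - eps) / n)
        assert abs(kept / n - (1 - eps)) <= 3 * se
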