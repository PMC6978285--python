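"""Shipped default configurations: registry, scales, CAPs, case-mix table.

Everything in this module is declarative data.  Item wording, decision-tree
algorithms and CAP trigger thresholds of the real instruments are
proprietary; the defaults below preserve every *published structural fact*
(instrument totals 396/405/141/46, the 330-item MH/CMH common core,
per-domain item counts, scale component lists and ranges, the CAP
applicability matrix) while the item namespace, tree shapes and trigger
thresholds are documented, replaceable stand-ins.
"""

from __future__ import annotations

from .errors import RegistryError

# --------------------------------------------------------------------------
# Registry: published per-domain item counts (MH, CMH, ESP, BMHS, FS, AS).
# Domain counts do not sum to the published instrument totals; the remainder
# is padded with an "unclassified" domain so the totals come out exact.
# --------------------------------------------------------------------------

DOMAIN_COUNTS: dict[str, tuple[int, int, int, int, int, int]] = {
    "administrative & tracking": (43, 39, 27, 22, 7, 6),
    "mental status indicators": (42, 40, 33, 8, 6, 0),
    "substance use/addictions": (17, 19, 10, 1, 0, 17),
    "harm to self/others": (13, 17, 12, 9, 11, 0),
    "behavior": (9, 6, 5, 2, 3, 0),
    "cognition": (8, 8, 5, 1, 0, 0),
    "functional status": (16, 23, 3, 0, 0, 0),
    "communication & vision": (4, 4, 1, 0, 0, 0),
    "physical health conditions": (40, 41, 0, 0, 0, 11),
    "stress & trauma": (19, 21, 1, 0, 1, 0),
    "medications": (5, 4, 4, 1, 0, 0),
    "service use & treatments": (36, 36, 2, 0, 0, 1),
    "control interventions": (13, 0, 0, 0, 0, 0),
    "nutritional status": (10, 10, 0, 0, 0, 0),
    "social relations": (12, 31, 9, 0, 5, 1),
    "employment, education & finances": (9, 9, 0, 0, 0, 0),
    "housing, home environment, living arrangements": (5, 10, 6, 3, 0, 0),
    "diagnoses": (30, 28, 16, 0, 0, 0),
}

_DOMAIN_KEY = {
    "administrative & tracking": "adm",
    "mental status indicators": "msi",
    "substance use/addictions": "sua",
    "harm to self/others": "hso",
    "behavior": "beh",
    "cognition": "cog",
    "functional status": "fun",
    "communication & vision": "cav",
    "physical health conditions": "phc",
    "stress & trauma": "str",
    "medications": "med",
    "service use & treatments": "sut",
    "control interventions": "cin",
    "nutritional status": "nut",
    "social relations": "soc",
    "employment, education & finances": "eef",
    "housing, home environment, living arrangements": "hhl",
    "diagnoses": "dxp",
    "unclassified": "unc",
}

# Named items: the ones scale and CAP defaults reference.  All live in the
# MH/CMH common core.  Tuples: (code, domain, max_code, on_esp, on_bmhs).
# Default codings: 0-3 symptom frequency, 0-4 ADL/IADL performance,
# 0-1 binary; deviations noted inline.
NAMED_ITEMS: list[tuple[str, str, int, bool, bool]] = [
    # Positive Symptoms Scale components (also on the police screener)
    ("hallucinations", "mental status indicators", 3, True, True),
    ("command_hallucinations", "mental status indicators", 3, True, True),
    ("delusions", "mental status indicators", 3, True, True),
    ("abnormal_thought", "mental status indicators", 3, True, True),
    # Negative Symptoms Scale components
    ("anhedonia", "mental status indicators", 3, True, False),
    ("withdrawal_activities", "mental status indicators", 3, True, False),
    ("lack_motivation", "mental status indicators", 3, True, False),
    ("reduced_social_interactions", "mental status indicators", 3, True, False),
    # Depressive Severity Index components
    ("sad_facial_expressions", "mental status indicators", 3, True, False),
    ("negative_statements", "mental status indicators", 3, True, False),
    ("self_deprecation", "mental status indicators", 3, True, False),
    ("guilt_shame", "mental status indicators", 3, True, False),
    ("hopelessness", "mental status indicators", 3, True, False),
    # Mania Scale components (sleep problems coded 0-2 so the scale max is 20)
    ("inflated_self_worth", "mental status indicators", 3, True, False),
    ("hyperarousal", "mental status indicators", 3, True, False),
    ("irritability", "mental status indicators", 3, True, False),
    ("increased_sociability", "mental status indicators", 3, True, False),
    ("pressured_speech", "mental status indicators", 3, True, False),
    ("labile_affect", "mental status indicators", 3, True, False),
    ("sleep_problems_hypomania", "mental status indicators", 2, True, False),
    # other mental-status items used by decision trees / CAPs
    ("insight", "mental status indicators", 2, True, False),
    ("decreased_energy", "mental status indicators", 3, True, False),
    ("sleep_disturbance", "mental status indicators", 3, True, False),
    # Aggressive Behavior Scale components
    ("verbal_abuse", "behavior", 3, True, False),
    ("physical_abuse", "behavior", 3, True, False),
    ("socially_inappropriate", "behavior", 3, True, False),
    ("resists_care", "behavior", 3, True, False),
    # Cognitive Performance Scale components
    ("daily_decision_making", "cognition", 3, True, False),
    ("short_term_memory", "cognition", 3, True, False),
    ("making_self_understood", "communication & vision", 3, True, False),
    # ADL Scale components (0-4 performance coding)
    ("personal_hygiene", "functional status", 4, True, False),
    ("locomotion", "functional status", 4, True, False),
    ("toilet_use", "functional status", 4, True, False),
    ("eating", "functional status", 4, True, False),
    # IADL Capacity components (meal preparation 0-6 so the scale max is 30)
    ("meal_preparation", "functional status", 6, False, False),
    ("ordinary_housework", "functional status", 4, False, False),
    ("managing_finances", "functional status", 4, False, False),
    ("managing_medications", "functional status", 4, False, False),
    ("phone_use", "functional status", 4, False, False),
    ("shopping", "functional status", 4, False, False),
    ("transportation", "functional status", 4, False, False),
    # harm to self / others
    ("violence_extreme_behavior", "harm to self/others", 3, True, False),
    ("violent_ideation", "harm to self/others", 3, True, False),
    ("intimidation_threats", "harm to self/others", 3, True, False),
    ("self_harm_ideation", "harm to self/others", 3, True, False),
    ("suicide_attempts", "harm to self/others", 1, True, False),
    ("suicide_plan", "harm to self/others", 1, True, False),
    ("others_concerned", "harm to self/others", 1, True, False),
    ("criminal_activity", "harm to self/others", 1, False, False),
    # substance use
    ("cage_cut_down", "substance use/addictions", 1, False, False),
    ("cage_angered", "substance use/addictions", 1, False, False),
    ("cage_guilt", "substance use/addictions", 1, False, False),
    ("cage_morning_use", "substance use/addictions", 1, False, False),
    ("tobacco_use", "substance use/addictions", 3, True, False),
    ("withdrawal_symptoms", "substance use/addictions", 3, True, False),
    ("misuse_prescription_meds", "substance use/addictions", 1, False, False),
    # physical health (pain items 0-2 so the Pain scale max is 4)
    ("pain_frequency", "physical health conditions", 2, False, False),
    ("pain_intensity", "physical health conditions", 2, False, False),
    ("falls", "physical health conditions", 3, False, False),
    ("bmi_problem", "physical health conditions", 1, False, False),
    ("eating_behavior_problem", "physical health conditions", 1, False, False),
    ("physical_activity_low", "physical health conditions", 2, False, False),
    # social relations
    ("lonely", "social relations", 3, False, False),
    ("conflict_with_others", "social relations", 3, False, False),
    ("family_overwhelmed", "social relations", 3, False, False),
    ("discharge_support_absent", "social relations", 1, False, False),
    # stress & trauma
    ("traumatic_life_event", "stress & trauma", 3, False, False),
    # service use & treatments
    ("control_intervention_recent", "service use & treatments", 1, False, False),
    ("prior_psych_admissions", "service use & treatments", 3, False, False),
    # employment, education & finances
    ("economic_hardship", "employment, education & finances", 1, False, False),
    ("education_employment_disruption", "employment, education & finances", 3, False, False),
    # medications
    ("med_nonadherence", "medications", 2, True, False),
]

_TOTALS = {"MH": 396, "CMH": 405, "ESP": 141, "BMHS": 46, "FS": 33, "AS": 35}


def default_registry_config() -> dict:
    """Build the shipped default registry config.

    Per-domain allocation follows the published counts; three documented
    adjustments reconcile internal inconsistencies in those counts:

    * the BMHS domain counts sum to 47 against a published total of 46 —
      the administrative count is trimmed from 22 to 21;
    * the ESP housing count (6) exceeds the MH housing count (5), breaking
      the ESP-within-common-core subset — one housing slot moves to the
      unclassified pad;
    * the ESP carries the four ADL items although its published functional
      count is 3 (the ADL Scale is listed for the ESP) — functional is 4.

    Remaining items up to the published totals are synthetic pads in the
    "unclassified" domain.
    """
    named_by_domain: dict[str, list[tuple[str, str, int, bool, bool]]] = {}
    for row in NAMED_ITEMS:
        named_by_domain.setdefault(row[1], []).append(row)

    items: list[dict] = []
    shared_total = esp_total = bmhs_total = 0
    mh_only_total = cmh_only_total = 0

    def lookback_for(domain: str) -> str:
        return "7-day" if domain == "service use & treatments" else "3-day"

    for domain, (mh_n, cmh_n, esp_n, bmhs_n, _fs, _as) in DOMAIN_COUNTS.items():
        key = _DOMAIN_KEY[domain]
        named = named_by_domain.get(domain, [])
        shared_quota = min(mh_n, cmh_n)
        if len(named) > shared_quota:
            raise RegistryError(f"domain {domain!r}: more named items than shared slots")
        if domain == "housing, home environment, living arrangements":
            esp_quota = min(esp_n, shared_quota)  # ESP housing capped at the common core
        else:
            esp_quota = min(esp_n, shared_quota)
        named_esp = [r for r in named if r[3]]
        esp_quota = max(esp_quota, len(named_esp))  # functional-status adjustment
        bmhs_quota = bmhs_n
        if domain == "administrative & tracking":
            bmhs_quota = 21  # published BMHS domain counts sum to 47, total is 46

        # shared pool: named items first, then synthetic pads
        shared_codes: list[tuple[str, int, bool]] = []  # (code, max_code, named_esp)
        for code, _d, max_code, on_esp, _b in named:
            shared_codes.append((code, max_code, on_esp))
        for i in range(shared_quota - len(named)):
            shared_codes.append((f"s_{key}_{i + 1:03d}", 3, False))

        # ESP membership: named-on-ESP items plus synthetic pads up to quota
        esp_members: list[str] = [c for c, _m, e in shared_codes if e]
        for code, _m, e in shared_codes:
            if len(esp_members) >= esp_quota:
                break
            if not e and code.startswith("s_"):
                esp_members.append(code)
        for code, _m, e in shared_codes:  # fallback: named items not flagged for ESP
            if len(esp_members) >= esp_quota:
                break
            if code not in esp_members:
                esp_members.append(code)
        if len(esp_members) != esp_quota:
            raise RegistryError(f"domain {domain!r}: cannot fill ESP quota {esp_quota}")

        # BMHS membership: named-on-BMHS first, then remaining ESP items in order
        named_bmhs = [c for c, _d, _m, _e, b in named if b]
        bmhs_members = list(named_bmhs)
        for code in esp_members:
            if len(bmhs_members) >= bmhs_quota:
                break
            if code not in bmhs_members:
                bmhs_members.append(code)
        if len(bmhs_members) != bmhs_quota:
            raise RegistryError(f"domain {domain!r}: cannot fill BMHS quota {bmhs_quota}")

        esp_set, bmhs_set = set(esp_members), set(bmhs_members)
        named_max = {c: m for c, _d, m, _e, _b in named}
        for code, max_code, _e in shared_codes:
            insts = ["MH", "CMH"]
            if code in esp_set:
                insts.append("ESP")
            if code in bmhs_set:
                insts.append("BMHS")
            items.append(
                {
                    "item_code": code,
                    "domain": domain,
                    "min_code": 0,
                    "max_code": named_max.get(code, max_code),
                    "lookback": lookback_for(domain),
                    "instruments": insts,
                }
            )
        for i in range(mh_n - shared_quota):
            items.append(
                {
                    "item_code": f"m_{key}_{i + 1:03d}",
                    "domain": domain,
                    "min_code": 0,
                    "max_code": 3,
                    "lookback": lookback_for(domain),
                    "instruments": ["MH"],
                }
            )
        for i in range(cmh_n - shared_quota):
            items.append(
                {
                    "item_code": f"c_{key}_{i + 1:03d}",
                    "domain": domain,
                    "min_code": 0,
                    "max_code": 3,
                    "lookback": lookback_for(domain),
                    "instruments": ["CMH"],
                }
            )
        shared_total += shared_quota
        esp_total += esp_quota
        bmhs_total += bmhs_quota
        mh_only_total += mh_n - shared_quota
        cmh_only_total += cmh_n - shared_quota

    # unclassified pads up to the published instrument totals
    shared_pad = 330 - shared_total
    mh_pad = (_TOTALS["MH"] - 330) - mh_only_total
    cmh_pad = (_TOTALS["CMH"] - 330) - cmh_only_total
    esp_pad = _TOTALS["ESP"] - esp_total
    bmhs_pad = _TOTALS["BMHS"] - bmhs_total
    if min(shared_pad, mh_pad, cmh_pad, esp_pad, bmhs_pad) < 0 or esp_pad > shared_pad:
        raise RegistryError("default registry pads are infeasible")
    for i in range(shared_pad):
        insts = ["MH", "CMH"]
        if i < esp_pad:
            insts.append("ESP")
            if i < bmhs_pad:
                insts.append("BMHS")
        items.append(
            {
                "item_code": f"s_unc_{i + 1:03d}",
                "domain": "unclassified",
                "min_code": 0,
                "max_code": 3,
                "lookback": "3-day",
                "instruments": insts,
            }
        )
    for i in range(mh_pad):
        items.append(
            {
                "item_code": f"m_unc_{i + 1:03d}",
                "domain": "unclassified",
                "min_code": 0,
                "max_code": 3,
                "lookback": "3-day",
                "instruments": ["MH"],
            }
        )
    for i in range(cmh_pad):
        items.append(
            {
                "item_code": f"c_unc_{i + 1:03d}",
                "domain": "unclassified",
                "min_code": 0,
                "max_code": 3,
                "lookback": "3-day",
                "instruments": ["CMH"],
            }
        )

    # supplements: count-only placeholders (AS admain trimmed 6 -> 5 so the
    # published 35-item total holds against domain counts summing to 36)
    for code_prefix, col, total in (("fs", 4, _TOTALS["FS"]), ("as", 5, _TOTALS["AS"])):
        emitted = 0
        for domain, counts in DOMAIN_COUNTS.items():
            n = counts[col]
            if code_prefix == "as" and domain == "administrative & tracking":
                n = 5
            for i in range(n):
                items.append(
                    {
                        "item_code": f"{code_prefix}_{_DOMAIN_KEY[domain]}_{i + 1:03d}",
                        "domain": domain,
                        "min_code": 0,
                        "max_code": 3,
                        "lookback": "3-day",
                        "instruments": [code_prefix.upper()],
                    }
                )
                emitted += 1
        if emitted != total:
            raise RegistryError(f"supplement {code_prefix.upper()}: built {emitted}, want {total}")

    return {
        "items": items,
        "default_lookbacks": {
            "MH": "3-day",
            "CMH": "3-day",
            "ESP": "24-hour",
            "BMHS": "24-hour",
            "FS": "3-day",
            "AS": "3-day",
        },
        "expected": {
            "MH": 396,
            "CMH": 405,
            "ESP": 141,
            "BMHS": 46,
            "MH&CMH": 330,
            "CMH-MH": 75,
            "MH-CMH": 66,
        },
    }


# --------------------------------------------------------------------------
# Scales: the thirteen published summary scales.  Sum-scale components and
# ranges are as published; the four decision trees are documented default
# shapes over the published component lists (the licensed algorithms are
# not public) that realize the full 0-6 output range.
# --------------------------------------------------------------------------

DEFAULT_SCALE_CONFIG: list[dict] = [
    {
        "name": "aggressive_behavior",
        "kind": "sum",
        "components": ["verbal_abuse", "physical_abuse", "socially_inappropriate", "resists_care"],
        "instruments": ["MH", "CMH", "ESP"],
    },
    {
        # alternative 0-8 coding of the same four behaviors (each capped at 2)
        "name": "aggressive_behavior_0_8",
        "kind": "sum",
        "components": ["verbal_abuse", "physical_abuse", "socially_inappropriate", "resists_care"],
        "component_cap": 2,
        "instruments": [],
    },
    {
        "name": "adl",
        "kind": "sum",
        "components": ["personal_hygiene", "locomotion", "toilet_use", "eating"],
        "instruments": ["MH", "CMH", "ESP"],
    },
    {
        "name": "negative_symptoms",
        "kind": "sum",
        "components": [
            "anhedonia",
            "withdrawal_activities",
            "lack_motivation",
            "reduced_social_interactions",
        ],
        "instruments": ["MH", "CMH", "ESP"],
    },
    {
        "name": "cage",
        "kind": "sum",
        "components": ["cage_cut_down", "cage_angered", "cage_guilt", "cage_morning_use"],
        "instruments": ["MH", "CMH"],
    },
    {
        "name": "depressive_severity",
        "kind": "sum",
        "components": [
            "sad_facial_expressions",
            "negative_statements",
            "self_deprecation",
            "guilt_shame",
            "hopelessness",
        ],
        "instruments": ["MH", "CMH", "ESP"],
    },
    {
        "name": "iadl",
        "kind": "sum",
        "components": [
            "meal_preparation",
            "ordinary_housework",
            "managing_finances",
            "managing_medications",
            "phone_use",
            "shopping",
            "transportation",
        ],
        "instruments": ["MH", "CMH"],  # not collected in the ESP
    },
    {
        "name": "mania",
        "kind": "sum",
        "components": [
            "inflated_self_worth",
            "hyperarousal",
            "irritability",
            "increased_sociability",
            "pressured_speech",
            "labile_affect",
            "sleep_problems_hypomania",
        ],
        "instruments": ["MH", "CMH", "ESP"],
    },
    {
        "name": "pain",
        "kind": "sum",
        "components": ["pain_frequency", "pain_intensity"],
        "instruments": ["MH", "CMH"],
    },
    {
        "name": "positive_symptoms",
        "kind": "sum",
        "components": ["hallucinations", "command_hallucinations", "delusions", "abnormal_thought"],
        "instruments": ["MH", "CMH", "ESP", "BMHS"],
    },
    {
        "name": "cognitive_performance",
        "kind": "decision_tree",
        "components": ["daily_decision_making", "short_term_memory", "making_self_understood", "eating"],
        "instruments": ["MH", "CMH", "ESP"],
        "tree": {
            "var": "item:daily_decision_making", "op": ">=", "value": 3,
            "then": {"var": "item:eating", "op": ">=", "value": 3, "then": 6, "else": 5},
            "else": {
                "var": "item:daily_decision_making", "op": ">=", "value": 2,
                "then": {"var": "item:short_term_memory", "op": ">=", "value": 2, "then": 4, "else": 3},
                "else": {
                    "var": "item:making_self_understood", "op": ">=", "value": 2,
                    "then": 2,
                    "else": {
                        "var": "item:short_term_memory", "op": ">=", "value": 1,
                        "then": 1,
                        "else": {
                            "var": "item:making_self_understood", "op": ">=", "value": 1,
                            "then": 1,
                            "else": {
                                "var": "item:daily_decision_making", "op": ">=", "value": 1,
                                "then": 1, "else": 0,
                            },
                        },
                    },
                },
            },
        },
    },
    {
        "name": "risk_harm_others",
        "kind": "decision_tree",
        "components": [
            "violence_extreme_behavior",
            "violent_ideation",
            "intimidation_threats",
            "insight",
            "delusions",
            "sleep_disturbance",
        ],
        "subscales": ["aggressive_behavior", "positive_symptoms"],
        "instruments": ["MH", "CMH", "ESP"],
        "tree": {
            "var": "item:violence_extreme_behavior", "op": ">=", "value": 2,
            "then": {"var": "item:violent_ideation", "op": ">=", "value": 2, "then": 6, "else": 5},
            "else": {
                "var": "item:intimidation_threats", "op": ">=", "value": 2,
                "then": {"var": "scale:aggressive_behavior", "op": ">=", "value": 4, "then": 4, "else": 3},
                "else": {
                    "var": "item:violent_ideation", "op": ">=", "value": 1,
                    "then": 2,
                    "else": {
                        "var": "item:delusions", "op": ">=", "value": 2,
                        "then": {"var": "item:insight", "op": ">=", "value": 1, "then": 2, "else": 1},
                        "else": {
                            "var": "scale:positive_symptoms", "op": ">=", "value": 6,
                            "then": 1,
                            "else": {
                                "var": "item:sleep_disturbance", "op": ">=", "value": 2,
                                "then": 1,
                                "else": {
                                    "var": "scale:aggressive_behavior", "op": ">=", "value": 1,
                                    "then": 1, "else": 0,
                                },
                            },
                        },
                    },
                },
            },
        },
    },
    {
        "name": "self_care_index",
        "kind": "decision_tree",
        "components": [
            "insight",
            "decreased_energy",
            "making_self_understood",
            "personal_hygiene",
            "anhedonia",
        ],
        "subscales": ["cognitive_performance", "positive_symptoms", "mania"],
        "instruments": ["MH", "CMH", "ESP"],
        "tree": {
            "var": "scale:cognitive_performance", "op": ">=", "value": 5,
            "then": 6,
            "else": {
                "var": "item:personal_hygiene", "op": ">=", "value": 3,
                "then": {"var": "scale:cognitive_performance", "op": ">=", "value": 2, "then": 5, "else": 4},
                "else": {
                    "var": "scale:positive_symptoms", "op": ">=", "value": 6,
                    "then": {"var": "item:insight", "op": ">=", "value": 1, "then": 4, "else": 3},
                    "else": {
                        "var": "item:decreased_energy", "op": ">=", "value": 2,
                        "then": {"var": "scale:mania", "op": ">=", "value": 9, "then": 3, "else": 2},
                        "else": {
                            "var": "item:making_self_understood", "op": ">=", "value": 2,
                            "then": 2,
                            "else": {
                                "var": "item:anhedonia", "op": ">=", "value": 1,
                                "then": 1,
                                "else": {
                                    "var": "item:personal_hygiene", "op": ">=", "value": 1,
                                    "then": 1, "else": 0,
                                },
                            },
                        },
                    },
                },
            },
        },
    },
    {
        "name": "self_harm_severity",
        "kind": "decision_tree",
        "components": [
            "self_harm_ideation",
            "suicide_attempts",
            "suicide_plan",
            "others_concerned",
        ],
        "subscales": ["depressive_severity", "positive_symptoms", "cognitive_performance"],
        "instruments": ["MH", "CMH", "ESP"],
        "tree": {
            "var": "item:suicide_attempts", "op": ">=", "value": 1,
            "then": {"var": "item:suicide_plan", "op": ">=", "value": 1, "then": 6, "else": 5},
            "else": {
                "var": "item:suicide_plan", "op": ">=", "value": 1,
                "then": 4,
                "else": {
                    "var": "item:self_harm_ideation", "op": ">=", "value": 2,
                    "then": {"var": "scale:depressive_severity", "op": ">=", "value": 8, "then": 4, "else": 3},
                    "else": {
                        "var": "item:self_harm_ideation", "op": ">=", "value": 1,
                        "then": 2,
                        "else": {
                            "var": "item:others_concerned", "op": ">=", "value": 1,
                            "then": {"var": "scale:depressive_severity", "op": ">=", "value": 4, "then": 2, "else": 1},
                            "else": {
                                "var": "scale:positive_symptoms", "op": ">=", "value": 6,
                                "then": 1,
                                "else": {
                                    "var": "scale:cognitive_performance", "op": ">=", "value": 3,
                                    "then": 1, "else": 0,
                                },
                            },
                        },
                    },
                },
            },
        },
    },
]


# --------------------------------------------------------------------------
# CAPs: the 21 published protocols with their level counts and per-instrument
# applicability.  MH and CMH each trigger 20 (they differ only on Informal
# Support vs Support Systems for Discharge); the ESP triggers the three
# safety protocols plus Smoking.  Trigger thresholds are documented,
# non-canonical defaults over the shipped scales and items.
# --------------------------------------------------------------------------

DEFAULT_CAP_CONFIG: list[dict] = [
    {
        "name": "Harm to Others",
        "group": "safety",
        "n_levels": 2,
        "level_focus": ["elevated risk", "high risk"],
        "applies_to": ["MH", "CMH", "ESP"],
        "rules": {
            "2": {"var": "scale:risk_harm_others", "op": ">=", "value": 4},
            "1": {"var": "scale:risk_harm_others", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Suicidality and Purposeful Self-Harm",
        "group": "safety",
        "n_levels": 2,
        "level_focus": ["elevated risk", "high risk"],
        "applies_to": ["MH", "CMH", "ESP"],
        "rules": {
            "2": {"var": "scale:self_harm_severity", "op": ">=", "value": 4},
            "1": {"var": "scale:self_harm_severity", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Self-Care",
        "group": "safety",
        "n_levels": 2,
        "level_focus": ["elevated risk", "high risk"],
        "applies_to": ["MH", "CMH", "ESP"],
        "rules": {
            "2": {"var": "scale:self_care_index", "op": ">=", "value": 4},
            "1": {"var": "scale:self_care_index", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Social Relationships",
        "group": "social life",
        "n_levels": 2,
        "level_focus": ["degree of isolation", "family dysfunction"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:lonely", "op": ">=", "value": 2},
            "1": {"var": "item:lonely", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Informal Support",
        "group": "social life",
        "n_levels": 2,
        "level_focus": ["type of support needed", "caregiver strain"],
        "applies_to": ["CMH"],
        "rules": {
            "2": {"var": "item:family_overwhelmed", "op": ">=", "value": 2},
            "1": {"var": "item:family_overwhelmed", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Support Systems for Discharge",
        "group": "social life",
        "n_levels": 1,
        "level_focus": ["availability of support on discharge"],
        "applies_to": ["MH"],
        "rules": {"1": {"var": "item:discharge_support_absent", "op": ">=", "value": 1}},
    },
    {
        "name": "Interpersonal Conflict",
        "group": "social life",
        "n_levels": 2,
        "level_focus": ["extent of conflict", "severe conflict"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:conflict_with_others", "op": ">=", "value": 2},
            "1": {"var": "item:conflict_with_others", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Traumatic Life Events",
        "group": "social life",
        "n_levels": 2,
        "level_focus": ["immediate safety", "ongoing impact"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:traumatic_life_event", "op": ">=", "value": 2},
            "1": {"var": "item:traumatic_life_event", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Criminal Activity",
        "group": "social life",
        "n_levels": 1,
        "level_focus": ["violent or non-violent criminal behavior"],
        "applies_to": ["MH", "CMH"],
        "rules": {"1": {"var": "item:criminal_activity", "op": ">=", "value": 1}},
    },
    {
        "name": "Personal Finances",
        "group": "economic issues",
        "n_levels": 2,
        "level_focus": ["economic hardship", "IADL capacity"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:economic_hardship", "op": ">=", "value": 1},
            "1": {"var": "item:managing_finances", "op": ">=", "value": 2},
        },
    },
    {
        "name": "Education and Employment",
        "group": "economic issues",
        "n_levels": 2,
        "level_focus": ["reduce risk", "support employment/education"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:education_employment_disruption", "op": ">=", "value": 2},
            "1": {"var": "item:education_employment_disruption", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Control Interventions",
        "group": "autonomy",
        "n_levels": 2,
        "level_focus": ["use in emergency situations", "use in non-emergency situations"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {
                "all": [
                    {"var": "item:control_intervention_recent", "op": ">=", "value": 1},
                    {"var": "scale:aggressive_behavior", "op": ">=", "value": 4},
                ]
            },
            "1": {"var": "item:control_intervention_recent", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Medication Management and Adherence",
        "group": "autonomy",
        "n_levels": 2,
        "level_focus": ["IADL & adherence", "stopped meds/side effects"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:med_nonadherence", "op": ">=", "value": 2},
            "1": {
                "any": [
                    {"var": "item:med_nonadherence", "op": ">=", "value": 1},
                    {"var": "item:managing_medications", "op": ">=", "value": 2},
                ]
            },
        },
    },
    {
        "name": "Rehospitalization",
        "group": "autonomy",
        "n_levels": 2,
        "level_focus": ["elevated risk", "high risk"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:prior_psych_admissions", "op": ">=", "value": 2},
            "1": {"var": "item:prior_psych_admissions", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Smoking",
        "group": "health promotion",
        "n_levels": 2,
        "level_focus": ["withdrawal symptoms", "encourage cessation"],
        "applies_to": ["MH", "CMH", "ESP"],
        "rules": {
            "2": {"var": "item:withdrawal_symptoms", "op": ">=", "value": 1},
            "1": {"var": "item:tobacco_use", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Substance Use",
        "group": "health promotion",
        "n_levels": 2,
        "level_focus": ["current problematic use", "prior problematic use"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "scale:cage", "op": ">=", "value": 2},
            "1": {"var": "scale:cage", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Weight Management",
        "group": "health promotion",
        "n_levels": 2,
        "level_focus": ["problem BMI", "problematic eating behaviors"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:bmi_problem", "op": ">=", "value": 1},
            "1": {"var": "item:eating_behavior_problem", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Exercise",
        "group": "health promotion",
        "n_levels": 2,
        "level_focus": ["physical activity", "presence of health concerns"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:physical_activity_low", "op": ">=", "value": 2},
            "1": {"var": "item:physical_activity_low", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Sleep Disturbance",
        "group": "health promotion",
        "n_levels": 2,
        "level_focus": ["sleep disturbance", "sleep disturbance with cognitive impairment"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {
                "all": [
                    {"var": "item:sleep_disturbance", "op": ">=", "value": 2},
                    {"var": "scale:cognitive_performance", "op": ">=", "value": 1},
                ]
            },
            "1": {"var": "item:sleep_disturbance", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Pain",
        "group": "health promotion",
        "n_levels": 2,
        "level_focus": ["treatment priority level", "treatment priority level"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "scale:pain", "op": ">=", "value": 3},
            "1": {"var": "scale:pain", "op": ">=", "value": 1},
        },
    },
    {
        "name": "Falls",
        "group": "health promotion",
        "n_levels": 2,
        "level_focus": ["elevated risk", "high risk"],
        "applies_to": ["MH", "CMH"],
        "rules": {
            "2": {"var": "item:falls", "op": ">=", "value": 2},
            "1": {"var": "item:falls", "op": ">=", "value": 1},
        },
    },
]


# --------------------------------------------------------------------------
# Case-mix: a documented toy grouper and CMI table for exercising the
# surrounding machinery (the licensed 47-group inpatient classifier is not
# public).  The table's CMI spread is 8.4:1, matching the published spread
# of the real system.
# --------------------------------------------------------------------------

DEFAULT_CMI_TABLE: dict[str, float] = {
    "COG0-PSY0": 0.5,
    "COG0-PSY1": 0.7,
    "COG0-PSY2": 0.9,
    "COG1-PSY0": 1.1,
    "COG1-PSY1": 1.4,
    "COG1-PSY2": 1.8,
    "COG2-PSY0": 2.3,
    "COG2-PSY1": 3.0,
    "COG2-PSY2": 4.2,
}
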