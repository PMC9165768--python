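"""Shared builders for hand-crafted vessels in unit tests."""

from fleetreform import VesselRecord


def make_vessel(vid="V1", flag="AAA", effort=None, score=0.5, **kw):
    base = dict(
        vessel_id=vid,
        flag_state=flag,
        vessel_class="trawler",
        length_m=30.0,
        gross_tonnage=200.0,
        engine_power_kw=800.0,
        effort_by_region=effort or {"21": 1_000_000.0},
        high_seas_fraction=0.0,
        distant_water_fraction=0.2,
        territorial_fraction=0.8,
        disputed_area=False,
        iuu_listed=False,
        stock_status=1.0,
        management_score=score,
        development_status="developed",
    )
    base.update(kw)
    return VesselRecord(**base)
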