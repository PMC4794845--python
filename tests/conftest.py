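import pytest

from dpmquant.psm_io import GroupDesign, Mod, PsmRecord


@pytest.fixture
def design() -> GroupDesign:
    return GroupDesign()


@pytest.fixture
def make_record():
    """Factory for valid PSM records with sensible defaults."""

    def _make(
        peptide="SAMPLEK",
        acc="P1",
        run="run1",
        decoy=False,
        conf=99.9,
        unused=5.0,
        areas=None,
        mods=(),
        prev="K",
        nxt="G",
    ) -> PsmRecord:
        areas = {"114": 100.0, "116": 120.0, "117": 90.0} if areas is None else areas
        return PsmRecord(
            run_id=run,
            peptide=peptide,
            protein_acc=acc,
            is_decoy=decoy,
            confidence_pct=conf,
            unused_score=unused,
            reporter_areas=areas,
            mods=tuple(
                Mod(*m) if not isinstance(m, Mod) else m for m in mods
            ),
            prev_aa=prev,
            next_aa=nxt,
        )

    return _make
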