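import numpy as np
import pytest

from hrdkit.genome import GenomeModel, PatientClinicalRecord


@pytest.fixture
def toy_genome():
    """A 100 Mb single-chromosome genome for hand-checkable arithmetic."""
    return GenomeModel(names=("chr1",), lengths={"chr1": 100_000_000})


@pytest.fixture
def small_genome():
    """Two short chromosomes (total 1 Mb) for per-basepair brute force."""
    return GenomeModel(names=("chr1", "chr2"), lengths={"chr1": 600_000, "chr2": 400_000})


def make_patient(pid, response="SD", pfs=4.0, pfs_event=True, tumor="ovarian",
                 prior_lines=3, os_months=12.0, os_event=True, histology="HGS"):
    return PatientClinicalRecord(
        patient_id=pid, tumor_type=tumor, histology=histology,
        prior_lines=prior_lines, best_response=response,
        pfs_months=pfs, pfs_event=pfs_event, os_months=os_months, os_event=os_event,
    )


@pytest.fixture
def trial_cohort():
    """A 73-patient cohort reproducing a phase-2 trial's printed response
    counts: 1 CR + 6 PR (ORR 9.6%), 46 SD (DCR 72.6%), 15 PD, 5 NE;
    responders split 4 endometrial / 3 ovarian; 28 patients with < 3 prior
    lines holding 6 of the 7 responses; 12 patients with PFS >= 9.08 months
    (twice the 4.54-month median)."""
    patients = []
    k = 0

    def add(response, tumor, prior, pfs):
        nonlocal k
        k += 1
        patients.append(make_patient(f"T{k:03d}", response=response, tumor=tumor,
                                     prior_lines=prior, pfs=pfs))

    # 7 responders: 4 endometrial, 3 ovarian; 6 with < 3 prior lines
    add("CR", "endometrial", 1, 14.0)
    for _ in range(3):
        add("PR", "endometrial", 2, 10.0)
    add("PR", "ovarian", 2, 9.5)
    add("PR", "ovarian", 2, 9.2)
    add("PR", "ovarian", 4, 13.0)
    # 46 SD: 5 long-term (PFS >= 9.08), 22 endometrial, 16 with < 3 lines
    for i in range(46):
        pfs = 9.1 if i < 5 else 3.0
        add("SD", "endometrial" if i < 22 else "ovarian", 2 if i < 16 else 3, pfs)
    # 15 PD, 3 with < 3 lines
    for i in range(15):
        add("PD", "ovarian", 2 if i < 3 else 3, 1.5)
    # 5 NE (4 ovarian + the single breast case), 3 with < 3 lines
    for i in range(5):
        add("NE", "breast" if i == 4 else "ovarian", 2 if i < 3 else 3, 0.5)
    assert len(patients) == 73
    assert sum(p.tumor_type == "endometrial" for p in patients) == 26
    assert sum(p.tumor_type == "ovarian" for p in patients) == 46
    assert sum(p.prior_lines < 3 for p in patients) == 28
    return patients
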