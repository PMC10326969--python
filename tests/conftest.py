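import pytest

from cas9repair import GenerativeParams, TargetSite, generate_targets, sample_screen


def make_site(seq: str, target_id: str = "t") -> TargetSite:
    """Embed an arbitrary ACGT sequence in a minimal valid construct by
    appending a PAM; coordinates of ``seq`` are unchanged."""
    full = seq + "CAGGTTTT"
    return TargetSite(target_id, full, 0, len(seq) + 1)


def site_with_flanks(distal: str, proximal: str) -> TargetSite:
    """A valid target whose cut-site flanks are exactly (distal, proximal)."""
    prefix = "ACGTACGTACGTACGT"  # 16bp
    seq = prefix + distal + proximal + "AT" + "TGG" + "ACGTAC"
    t = TargetSite("flank", seq, 0, 20)
    assert t.distal_flank == distal and t.proximal_flank == proximal
    return t


@pytest.fixture(scope="session")
def gattaca() -> TargetSite:
    """23-mer with pam_start=20, cut at 17; flanks are T (distal), C (proximal)."""
    return TargetSite("gattaca", "GATTACAGGATCCTAGTCATTGG", 0, 20)


@pytest.fixture(scope="session")
def atgc_site() -> TargetSite:
    """Repeat-free neighbourhood around the cut: no deletion window that
    touches the cut can shift, so directionality examples are exact."""
    return TargetSite("atgc", "ATGCATGCATGCATGCATGCTGGA", 0, 20)


@pytest.fixture(scope="session")
def small_screen():
    """A 30-target screen with control plus two strong knockouts, reused by
    read-count-level unit tests."""
    params = GenerativeParams(n_targets=30, depth_median=2000, timepoints=("d7",))
    targets = generate_targets(params, seed=2)
    dataset, truth = sample_screen(
        targets, params, seed=3, lines=["control", "Nbn", "Lig4"]
    )
    return params, targets, dataset, truth
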