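species_a	species_b	my
dm3	droSim1	5
dm3	droSec1	5
dm3	droYak2	10
dm3	droEre1	10
dm3	droAna2	14
dm3	dp3	27
dm3	droPer1	27
dm3	droMoj2	40
dm3	droVir2	40
dm3	droGri1	40
droSim1	droSec1	3
droSim1	droYak2	10
droSim1	droEre1	10
droSim1	droAna2	14
droSim1	dp3	27
droSim1	droPer1	27
droSim1	droMoj2	40
droSim1	droVir2	40
droSim1	droGri1	40
droSec1	droYak2	10
droSec1	droEre1	10
droSec1	droAna2	14
droSec1	dp3	27
droSec1	droPer1	27
droSec1	droMoj2	40
droSec1	droVir2	40
droSec1	droGri1	40
droYak2	droEre1	8
droYak2	droAna2	14
droYak2	dp3	27
droYak2	droPer1	27
droYak2	droMoj2	40
droYak2	droVir2	40
droYak2	droGri1	40
droEre1	droAna2	14
droEre1	dp3	27
droEre1	droPer1	27
droEre1	droMoj2	40
droEre1	droVir2	40
droEre1	droGri1	40
droAna2	dp3	27
droAna2	droPer1	27
droAna2	droMoj2	40
droAna2	droVir2	40
droAna2	droGri1	40
dp3	droPer1	5
dp3	droMoj2	40
dp3	droVir2	40
dp3	droGri1	40
droPer1	droMoj2	40
droPer1	droVir2	40
droPer1	droGri1	40
droMoj2	droVir2	25
droMoj2	droGri1	30
droVir2	droGri1	30
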