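# Published Shannon information totals (bits) of six structural alignment
# benchmarks under fifteen substitution matrices; inputs for rank arithmetic.
matrix	HOMSTRAD	MATTBENCH	SABMARK-Sup	SABMARK-Twi	SCOP1	SCOP2
PAM	11531556.4	9143136.9	23574085.5	11310226.0	84925406.9	82757945.5
JTT	11481203.2	9072068.6	23450831.6	11251914.3	84353986.5	82218532.0
BLOSUM	11437552.8	9037049.8	23373908.1	11228043.6	84174710.8	81995179.3
JO	11476518.5	9118266.0	23501361.5	11290056.3	84567477.8	82405562.0
WAG	11419186.0	9052722.9	23400017.0	11243242.0	84141633.8	81996154.3
VTML	11423498.2	9035903.4	23377505.0	11230624.1	84075908.5	81925302.7
LG	11464263.6	9049040.6	23411713.3	11235389.2	84255656.9	82090289.0
MIQS	11422215.4	9040480.8	23385242.8	11236323.3	84076742.8	81927707.6
PFASUM	11412888.2	9039799.4	23379074.4	11236572.3	84040519.3	81902713.6
MMLHOMSTRAD	11405604.7	9035317.6	23365151.2	11230184.9	84026302.3	81873575.9
MMLMATTBENCH	11426344.1	9025882.4	23355215.8	11217219.1	84050927.4	81886796.3
MMLSABMARK-Sup	11424135.9	9031315.9	23346025.4	11212252.7	84067892.9	81889152.3
MMLSABMARK-Twi	11442781.7	9035720.5	23356054.5	11211360.9	84155701.5	81962307.9
MMLSCOP1	11413295.6	9029682.8	23355235.9	11221295.6	83996796.0	81848381.0
MMLSCOP2	11413725.3	9028667.52	23349826.8	11218205.6	83999536.4	81840654.6
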