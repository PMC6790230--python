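specimen_id,piece_index,total_length_um,head_length_um,head_width_um,stage_label,source
Dip-00640,1,2676.177,145.201,105.129,1,table2
GPIH-0247/8,,3346.186,165.624,115.993,1,table2
PED-4748,3,2283.494,99.005,87.693,1,table2
Dip-00656,,2067,166,115,1,table2
Dip-00640,2,2151.442,186.238,162.515,2,table2
Dip-00640,3,2693.354,209.082,178.836,2,table2
Dip-00640,4,2405.655,171.311,155.919,2,table2
GPIH-3706 W,,2957.863,190.825,180.487,2,table2
BI2350,,3909.86,235.719,155.103,2,table2
GPIH-0247,7,3034.273,195.118,166.481,2,table2
PED-4748,1,5048.093,309.328,171.883,2,table2
PED-4970,,4591.883,233.701,156.178,2,table2
Dip-00656,2,2784,181,192,2,table2
Dip-00655,1,2364,139,145,2,table2
Dip-00649,1,5166,178,181,2,table2
GPIH-0247,9,3,320.337,259.113,3,table2
PED-4748,2,5207.932,388.551,246.06,3,table2
PED-4748,4,10222.51,NA,191.139,3,table2
PED-4965,,7027.351,319.331,218.775,3,table2
PED-5695,,5503.7,284.294,230.87,3,table2
Dip-00639,,7609.245,306.751,295.106,3,table2
Dip-00658,,8139,376,239,3,table2
Dip-00656,1,5693,266,240,3,table2
Dip-00655,2,2344,225,227,3,table2
Dip-00649,2,8385,352,277,3,table2
GPIH-0247,2,3929.665,512.765,418.808,4,table2
GPIH-0247,1,5328.197,NA,NA,NA,table2
GPIH-0247,3,4150.859,NA,NA,NA,table2
GPIH-0247,4,4898.89,NA,NA,NA,table2
GPIH-0247,5,1819.851,NA,NA,NA,table2
GPIH-0247,6,3486.205,NA,NA,NA,table2
GPIH-l-7592,1,7194.75,NA,NA,NA,table2
GPIH-l-7592,2,6096.312,NA,NA,NA,table2
GPIH-l-7592,3,5701.261,NA,NA,NA,table2
GPIH-l-7592,4,6454.761,NA,NA,NA,table2
GPIH-l-7592,5,4017.086,NA,NA,NA,table2
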