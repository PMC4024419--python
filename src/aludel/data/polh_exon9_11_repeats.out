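score %div %del %ins query begin end (left) strand repeat class/family begin end (left) id
1692 13.5 0.4 0.4 chr6:POLH:43572521+43581878 657 893 (8465) C AluJr SINE/Alu (2) 310 74 1
2266 10.4 0.3 4.3 chr6:POLH:43572521+43581878 925 1240 (8118) C AluSq SINE/Alu (9) 304 1 2
658 26.3 8.6 4.6 chr6:POLH:43572521+43581878 1267 1581 (7777) C L1MA8 LINE/L1 (25) 6266 5940 3
2432 12.0 0.0 0.0 chr6:POLH:43572521+43581878 1644 1944 (7414) C AluSx1 SINE/Alu (10) 302 2 4
3529 14.9 6.9 4.2 chr6:POLH:43572521+43581878 1958 2302 (7056) C L1MB8 LINE/L1 (0) 6178 5821 5
2464 10.8 0.0 0.0 chr6:POLH:43572521+43581878 2303 2609 (6749) C AluSc5 SINE/Alu (2) 307 1 6
3529 16.1 7.0 4.4 chr6:POLH:43572521+43581878 2610 3080 (6278) C L1MB8 LINE/L1 (342) 5820 5323 5
2287 9.2 5.5 0.0 chr6:POLH:43572521+43581878 3081 3372 (5986) + AluSq2 SINE/Alu 1 308 (5) 7
1739 17.8 10.7 1.8 chr6:POLH:43572521+43581878 3373 3510 (5848) C L1MB8 LINE/L1 (829) 5333 5170 5
810 18.7 1.2 7.0 chr6:POLH:43572521+43581878 3744 3909 (5449) C AluJo SINE/Alu (19) 293 137 8
535 29.6 9.7 1.4 chr6:POLH:43572521+43581878 3990 4509 (4849) + L2a LINE/L2 (2804) 3365 (61) 9
2528 10.0 0.0 1.0 chr6:POLH:43572521+43581878 5271 5581 (3777) C AluSx1 SINE/Alu (4) 308 1 10
13 10.0 5.9 2.8 chr6:POLH:43572521+43581878 5582 5615 (3743) + (TCTTTA)n Simple_repeat 1 36 (0) 11
684 5.6 0.0 0.0 chr6:POLH:43572521+43581878 6162 6233 (3125) + AluSq10 SINE/Alu 1 72 (241) 12
2510 10.3 0.0 0.0 chr6:POLH:43572521+43581878 6991 7300 (2058) + AluSq2 SINE/Alu 1 310 (3) 13
2679 7.0 0.0 0.0 chr6:POLH:43572521+43581878 7564 7863 (1495) C AluSq SINE/Alu (13) 300 1 14
2503 8.4 0.7 0.0 chr6:POLH:43572521+43581878 8018 8313 (1045) C AluSg SINE/Alu (11) 299 2 15
214 24.7 18.6 1.0 chr6:POLH:43572521+43581878 8598 8683 (675) + MER5A DNA/hAT-Charlie 2 102 (87) 16
196 16.1 0.0 0.0 chr6:POLH:43572521+43581878 8684 8714 (644) + MER5A DNA/hAT-Charlie (159) 189 (0) 17
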