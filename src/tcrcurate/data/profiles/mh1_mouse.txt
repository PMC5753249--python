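# tcrcurate consensus numbering profile (implementer-constructed)
name: mh1_mouse
chain_type: MH1
species: mouse
kind: g_domain
positions: 1 2 3 4 5 6 7 8 9 10 11 12 13 14 15 16 17 18 19 20 21 22 23 24 25 26 27 28 29 30 31 32 33 34 35 36 37 38 39 40 41 42 43 44 45 46 47 48 49 50 51 52 53 54 55 56 57 58 59 60 61 62 63 64 65 66 67 68 69 70 71 72 73 74 75 76 77 78 79 80 81 82 83 84 85 86 87 88 89 90 1001 1002 1003 1004 1005 1006 1007 1008 1009 1010 1011 1012 1013 1014 1015 1016 1017 1018 1019 1020 1021 1022 1023 1024 1025 1026 1027 1028 1029 1030 1031 1032 1033 1034 1035 1036 1037 1038 1039 1040 1041 1042 1043 1044 1045 1046 1047 1048 1049 1050 1051 1052 1053 1054 1055 1056 1057 1058 1059 1060 1061 1062 1063 1064 1065 1066 1067 1068 1069 1070 1071 1072 1073 1074 1075 1076 1077 1078 1079 1080 1081 1082 1083 1084 1085 1086 1087 1088 1089 1090
sequence: ASHSMRYFFTSVSRPGRGEPRFISVGYVDDTQFVRFDSDAASQRMETRAPWIEQEGPEYWDRNTRNVKAGSQTDRVDLGTLRGYYNQSEASHNVQRMYGCDVGSDWRFLRGYHQYQYDGKDYIALKEDLRSWTAADMAAQTTKHKWEAAHVAEQLRAYLEGSCVEWLRRYLENGKETLQR
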