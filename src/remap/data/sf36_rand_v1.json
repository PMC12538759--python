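{
  "version": "rand-v1/1.0",
  "description": "RAND 36-Item Health Survey 1.0 item recoding table and subscale membership. Each raw response is recoded to a 0-100 score; a subscale is the mean of its non-missing recoded items.",
  "recode": {
    "1": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0},
    "2": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0},
    "3": {"1": 0, "2": 50, "3": 100},
    "4": {"1": 0, "2": 50, "3": 100},
    "5": {"1": 0, "2": 50, "3": 100},
    "6": {"1": 0, "2": 50, "3": 100},
    "7": {"1": 0, "2": 50, "3": 100},
    "8": {"1": 0, "2": 50, "3": 100},
    "9": {"1": 0, "2": 50, "3": 100},
    "10": {"1": 0, "2": 50, "3": 100},
    "11": {"1": 0, "2": 50, "3": 100},
    "12": {"1": 0, "2": 50, "3": 100},
    "13": {"1": 0, "2": 100},
    "14": {"1": 0, "2": 100},
    "15": {"1": 0, "2": 100},
    "16": {"1": 0, "2": 100},
    "17": {"1": 0, "2": 100},
    "18": {"1": 0, "2": 100},
    "19": {"1": 0, "2": 100},
    "20": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0},
    "21": {"1": 100, "2": 80, "3": 60, "4": 40, "5": 20, "6": 0},
    "22": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0},
    "23": {"1": 100, "2": 80, "3": 60, "4": 40, "5": 20, "6": 0},
    "24": {"1": 0, "2": 20, "3": 40, "4": 60, "5": 80, "6": 100},
    "25": {"1": 0, "2": 20, "3": 40, "4": 60, "5": 80, "6": 100},
    "26": {"1": 100, "2": 80, "3": 60, "4": 40, "5": 20, "6": 0},
    "27": {"1": 100, "2": 80, "3": 60, "4": 40, "5": 20, "6": 0},
    "28": {"1": 0, "2": 20, "3": 40, "4": 60, "5": 80, "6": 100},
    "29": {"1": 0, "2": 20, "3": 40, "4": 60, "5": 80, "6": 100},
    "30": {"1": 100, "2": 80, "3": 60, "4": 40, "5": 20, "6": 0},
    "31": {"1": 0, "2": 20, "3": 40, "4": 60, "5": 80, "6": 100},
    "32": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
    "33": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
    "34": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0},
    "35": {"1": 0, "2": 25, "3": 50, "4": 75, "5": 100},
    "36": {"1": 100, "2": 75, "3": 50, "4": 25, "5": 0}
  },
  "subscales": {
    "PF": ["3", "4", "5", "6", "7", "8", "9", "10", "11", "12"],
    "RP": ["13", "14", "15", "16"],
    "RE": ["17", "18", "19"],
    "VT": ["23", "27", "29", "31"],
    "MH": ["24", "25", "26", "28", "30"],
    "SF": ["20", "32"],
    "BP": ["21", "22"],
    "GH": ["1", "33", "34", "35", "36"]
  }
}
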